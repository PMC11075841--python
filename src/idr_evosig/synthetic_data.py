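"""Synthetic trees, alignments, score traces, and trait matrices.

The generator reproduces the statistical structure the analysis assumes —
not realistic protein evolution.  Trees come from a pure-birth process;
alignments evolve under a reversible substitution model with per-site rate
categories and a deletion-only indel process (gap runs with geometric
lengths in fixed alignment coordinates, so nested-deletion scenarios arise
naturally); disorder score traces are a logistic function of windowed
hydrophilicity plus a tree-correlated species offset and white noise, so
scores co-vary with composition and diverge with tree distance; trait
matrices are exact draws from the BM or stationary-OU tip distribution.
Fixture bundles are self-describing: generating parameters are written
beside the data.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.linalg import expm

from .alignment import ScoredAlignment, write_msa_fasta, write_score_tsv
from .feature_lib import KYTE_DOOLITTLE
from .tree import PhyloTree, TreeNode

__all__ = [
    "SimSpec",
    "sample_tree",
    "simulate_trait_matrix",
    "simulate_msa",
    "simulate_score_traces",
    "write_bundle",
]

# residue frequencies loosely echoing a disorder-enriched composition
_DEFAULT_FREQS = {
    "A": 0.074, "C": 0.009, "D": 0.050, "E": 0.065, "F": 0.030,
    "G": 0.066, "H": 0.025, "I": 0.040, "K": 0.055, "L": 0.075,
    "M": 0.020, "N": 0.050, "P": 0.065, "Q": 0.060, "R": 0.050,
    "S": 0.095, "T": 0.060, "V": 0.050, "W": 0.006, "Y": 0.020,
}


@dataclass
class SimSpec:
    """Parameters of one synthetic dataset."""

    n_tips: int = 12
    tree_model: str = "pure_birth"
    msa_length: int = 300
    site_rate_categories: list = field(default_factory=lambda: [(0.5, 0.5), (1.5, 0.5)])
    indel_rate: float = 0.02  # events per unit branch length per sequence
    mean_gap_length: float = 8.0
    trait_model: str = "BM"
    trait_params: dict = field(default_factory=lambda: {"sigma2": 1.0, "alpha": 1.0, "mu": 0.0})
    seed: int = 0
    freqs: dict = field(default_factory=lambda: dict(_DEFAULT_FREQS))

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.msa_length < 1:
            raise ValueError("msa_length must be >= 1")
        weights = [w for _, w in self.site_rate_categories]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("site rate category weights must sum to 1")
        if any(r < 0 for r, _ in self.site_rate_categories):
            raise ValueError("site rates must be >= 0")
        if self.indel_rate < 0 or self.mean_gap_length <= 0:
            raise ValueError("indel_rate >= 0 and mean_gap_length > 0 required")
        if self.tree_model != "pure_birth":
            raise ValueError(f"unknown tree model {self.tree_model!r}")
        if self.trait_model not in ("BM", "OU"):
            raise ValueError(f"unknown trait model {self.trait_model!r}")


def sample_tree(n_tips: int, seed: int, birth_rate: float = 1.0) -> PhyloTree:
    """Pure-birth (Yule) tree with tips sp1..spN and positive branch lengths."""
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    active = [TreeNode(length=0.0), TreeNode(length=0.0)]
    root.children = list(active)
    while len(active) < n_tips:
        wait = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node.length += wait
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        kids = [TreeNode(length=0.0), TreeNode(length=0.0)]
        parent.children = kids
        active.extend(kids)
    final = rng.exponential(1.0 / (birth_rate * n_tips))
    for node in active:
        node.length += final

    counter = [0]

    def label(node: TreeNode):
        for child in node.children:
            label(child)
        if not node.children:
            counter[0] += 1
            node.label = f"sp{counter[0]}"

    label(root)
    return PhyloTree(root)


def simulate_trait_matrix(
    tree: PhyloTree, model: str, params: dict, n_reps: int, seed: int
) -> np.ndarray:
    """I.i.d. draws from the model's tip distribution, one replicate per row.

    BM: MVN(mu * 1, sigma2 * C) with C the shared-path-length matrix.
    OU (stationary): MVN(mu * 1, (sigma2 / (2 alpha)) * exp(-alpha * d)).
    """
    sigma2 = float(params.get("sigma2", 1.0))
    mu = float(params.get("mu", 0.0))
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    d0 = tree.dist_matrix()
    zero = np.argwhere((d0 <= 0) & ~np.eye(len(d0), dtype=bool))
    if zero.size:
        labels = tree.tip_labels
        i, j = zero[0]
        raise ValueError(
            f"tip covariance not positive definite: tips {labels[i]!r} and "
            f"{labels[j]!r} are at zero tree distance"
        )
    if model == "BM":
        cov = sigma2 * tree.cov_matrix()
    elif model == "OU":
        alpha = float(params.get("alpha", 1.0))
        if alpha <= 0:
            raise ValueError("alpha must be > 0 for OU")
        cov = (sigma2 / (2.0 * alpha)) * np.exp(-alpha * tree.dist_matrix())
    else:
        raise ValueError(f"unknown model {model!r}")
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        d = tree.dist_matrix()
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        labels = tree.tip_labels
        raise ValueError(
            f"tip covariance not positive definite; tips {labels[i]!r} and "
            f"{labels[j]!r} are at zero distance"
        )
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_reps, len(tree.tip_labels)))
    return mu + Z @ L.T


def _rate_matrix(freqs: np.ndarray) -> np.ndarray:
    """Uniform-exchangeability reversible generator, mean rate 1."""
    k = len(freqs)
    Q = np.tile(freqs, (k, 1)).astype(float)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(freqs @ np.diag(Q))
    return Q / mean_rate


def simulate_msa(tree: PhyloTree, spec: SimSpec) -> ScoredAlignment:
    """Evolve an alignment along the tree (scores absent).

    Residues evolve under a reversible model with the spec's site-rate
    categories; deletions are Poisson events per branch that gap a
    geometric-length run of columns for the whole subtree below.
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = sorted(spec.freqs)
    freqs = np.array([spec.freqs[a] for a in alphabet])
    freqs = freqs / freqs.sum()
    Q = _rate_matrix(freqs)
    L = spec.msa_length
    rates = np.array([r for r, _ in spec.site_rate_categories])
    weights = np.array([w for _, w in spec.site_rate_categories])
    site_rate = rates[rng.choice(len(rates), size=L, p=weights)]

    root_states = rng.choice(len(alphabet), size=L, p=freqs)
    tips = [n for n in tree.postorder() if n.is_tip]
    seqs: dict[int, np.ndarray] = {}
    gaps: dict[int, np.ndarray] = {}

    # transition matrices cached per (branch length, rate)
    pmat_cache: dict[float, np.ndarray] = {}

    def pmat(t: float) -> np.ndarray:
        P = pmat_cache.get(t)
        if P is None:
            P = expm(Q * t)
            P = np.clip(P, 0.0, None)
            P /= P.sum(axis=1, keepdims=True)
            pmat_cache[t] = P
        return P

    def evolve(node, states: np.ndarray, gap: np.ndarray):
        if node is not tree.root:
            new = states.copy()
            for r in np.unique(site_rate):
                cols = np.nonzero(site_rate == r)[0]
                if r == 0 or node.length == 0:
                    continue
                P = pmat(node.length * float(r))
                cum = np.cumsum(P[states[cols]], axis=1)
                u = rng.random(len(cols))
                new[cols] = (u[:, None] < cum).argmax(axis=1)
            states = new
            gap = gap.copy()
            n_events = rng.poisson(spec.indel_rate * node.length)
            for _ in range(n_events):
                glen = min(L, int(rng.geometric(1.0 / spec.mean_gap_length)))
                start = int(rng.integers(0, max(1, L - glen + 1)))
                gap[start : start + glen] = True
        if node.is_tip:
            seqs[id(node)] = states
            gaps[id(node)] = gap
        else:
            for child in node.children:
                evolve(child, states, gap)

    evolve(tree.root, root_states, np.zeros(L, dtype=bool))

    species, rows = [], []
    for i, node in enumerate(tips):
        chars = np.array(list(alphabet))[seqs[id(node)]]
        chars[gaps[id(node)]] = "-"
        species.append(node.label)
        rows.append("".join(chars))
    return ScoredAlignment("synthetic", species, rows)


def simulate_score_traces(
    msa: ScoredAlignment,
    tree: PhyloTree,
    seed: int,
    gain: float = 3.0,
    bias: float = 0.0,
    offset_sd: float = 0.5,
    offset_alpha: float = 1.0,
    noise_sd: float = 0.1,
    window: int = 11,
) -> ScoredAlignment:
    """Attach per-residue disorder scores in [0, 1] to an alignment.

    score = logistic(gain * windowed hydrophilicity + bias + species offset
    + white noise); the species offsets are one stationary-OU draw on the
    tree, so score divergence accumulates with tree distance.  Zeroing
    ``offset_sd`` and ``noise_sd`` makes the trace a deterministic function
    of the sequence.
    """
    if msa.n_species < 2:
        raise ValueError("need at least 2 sequences")
    rng = np.random.default_rng(seed)
    if offset_sd > 0:
        offsets = simulate_trait_matrix(
            tree,
            "OU",
            {"sigma2": 2.0 * offset_alpha * offset_sd**2, "alpha": offset_alpha, "mu": 0.0},
            1,
            int(rng.integers(2**31 - 1)),
        )[0]
        offset_by_sp = dict(zip(tree.tip_labels, offsets))
    else:
        offset_by_sp = {sp: 0.0 for sp in tree.tip_labels}

    # hydrophilicity in roughly [-1, 1]: negated, scaled Kyte-Doolittle
    hphil = {a: -v / 4.5 for a, v in KYTE_DOOLITTLE.items()}
    half = window // 2
    scores = np.full((msa.n_species, msa.n_columns), np.nan)
    for i, sp in enumerate(msa.species):
        row = msa.rows[i]
        idx = [j for j, c in enumerate(row) if c != "-"]
        if not idx:
            continue
        seq = [row[j] for j in idx]
        h = np.array([hphil.get(c, 0.0) for c in seq])
        padded = np.pad(h, half, mode="edge")
        smooth = np.convolve(padded, np.ones(window) / window, "valid")
        z = gain * smooth + bias + offset_by_sp.get(sp, 0.0)
        if noise_sd > 0:
            z = z + rng.normal(0.0, noise_sd, size=len(z))
        vals = 1.0 / (1.0 + np.exp(-z))
        scores[i, idx] = vals
    return ScoredAlignment(
        msa.alignment_id, msa.species, msa.rows, scores=scores, missing_mask=msa.missing_mask
    )


def write_bundle(out_dir, spec: SimSpec, n_alignments: int = 1) -> PhyloTree:
    """Write a self-describing fixture bundle: tree, FASTAs, score TSVs, params."""
    os.makedirs(out_dir, exist_ok=True)
    tree = sample_tree(spec.n_tips, spec.seed)
    with open(os.path.join(out_dir, "tree.nwk"), "w") as fh:
        fh.write(tree.to_newick() + "\n")
    rng = np.random.default_rng(spec.seed)
    for k in range(n_alignments):
        sub = SimSpec(**{**asdict(spec), "seed": int(rng.integers(2**31 - 1))})
        aln = simulate_msa(tree, sub)
        aln.alignment_id = f"aln{k:04d}"
        aln = simulate_score_traces(aln, tree, seed=int(rng.integers(2**31 - 1)))
        write_msa_fasta(aln, os.path.join(out_dir, f"{aln.alignment_id}.fasta"))
        write_score_tsv(aln, os.path.join(out_dir, f"{aln.alignment_id}.scores.tsv"))
    with open(os.path.join(out_dir, "params.json"), "w") as fh:
        json.dump(asdict(spec) | {"n_alignments": n_alignments}, fh, indent=1)
    return tree
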