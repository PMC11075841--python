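"""Reversible substitution models, column rates, and indel characters.

A time-reversible model is parameterized by stationary frequencies pi and a
symmetric exchangeability matrix S with zero diagonal: the rate of change
from state i to state j is r_ij = s_ij * pi_j, and the generator is
normalized so the expected substitution rate at stationarity is 1, which
makes branch lengths expected substitutions per column.  Likelihoods are
computed with Felsenstein's pruning algorithm under a discrete rate mixture
(optional invariant class plus discrete-gamma categories); per-column rates
are posterior means over the categories.  Per-region divergence is measured
against a scaled copy of the reference species tree: the reported rate is
the column's posterior-mean rate times the fitted-to-reference tree-length
ratio.

Indel divergence uses a binary presence/absence coding of gap runs: every
maximal run of gap symbols with a unique (start, stop) becomes a character;
a sequence is coded 1 if it carries exactly that run or the run is strictly
nested inside one of its longer runs.  A two-state reversible model with an
ascertainment correction (all-absent patterns are unobservable) yields
per-character rates, each split half onto its start and stop columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import gamma as gamma_dist

from .alignment import GAP, STANDARD_AA, ScoredAlignment
from .region_calling import Region
from .tree import PhyloTree, prune_to_species

__all__ = [
    "ReversibleModel",
    "RegionRates",
    "IndelCharacterAlignment",
    "rate_matrix",
    "log10_ratio_matrices",
    "discrete_gamma_rates",
    "sample_meta_alignment",
    "fit_reversible_model",
    "fit_branch_scale_and_site_rates",
    "region_average_aa_rate",
    "encode_indel_characters",
    "fit_indel_rates",
    "partition_alignment",
]


@dataclass
class ReversibleModel:
    states: str | list[str]
    freqs: np.ndarray  # stationary frequencies, simplex
    exchangeabilities: np.ndarray  # symmetric, zero diagonal, >= 0
    rate_categories: list = field(default_factory=lambda: [(1.0, 1.0)])

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        k = len(self.states)
        if self.freqs.shape != (k,) or self.exchangeabilities.shape != (k, k):
            raise ValueError("inconsistent model dimensions")
        if not np.allclose(self.exchangeabilities, self.exchangeabilities.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if abs(self.freqs.sum() - 1.0) > 1e-8 or (self.freqs < 0).any():
            raise ValueError("freqs must lie on the simplex")
        w = np.array([w for _, w in self.rate_categories])
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("rate category weights must sum to 1")

    @property
    def k(self) -> int:
        return len(self.states)

    def mean_category_rate(self) -> float:
        return float(sum(r * w for r, w in self.rate_categories))


@dataclass
class RegionRates:
    region_id: str
    aa_rate: float
    indel_rate: float
    scale_factor: float


@dataclass
class IndelCharacterAlignment:
    characters: list  # (start, stop) half-open column intervals, unique
    species: list
    coding: np.ndarray  # (n_species, n_characters) in {0, 1}


# ---------------------------------------------------------------------------
# generators and mixtures


def rate_matrix(model: ReversibleModel, normalize: bool = True) -> np.ndarray:
    """Generator Q with q_ij = s_ij * pi_j, diagonal = -row sum.

    With ``normalize`` the matrix is scaled so sum_i pi_i * (-q_ii) = 1.
    Detailed balance pi_i q_ij = pi_j q_ji holds by construction.
    """
    Q = model.exchangeabilities * model.freqs[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalize:
        mean_rate = -float(model.freqs @ np.diag(Q))
        if mean_rate <= 0:
            raise ValueError("degenerate model: zero mean rate")
        Q = Q / mean_rate
    return Q


def log10_ratio_matrices(m_disorder: np.ndarray, m_order: np.ndarray) -> np.ndarray:
    """Elementwise log10(m_d / m_o); non-positive cells come back NaN."""
    a = np.asarray(m_disorder, dtype=float)
    b = np.asarray(m_order, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    out = np.full(a.shape, np.nan)
    ok = (a > 0) & (b > 0)
    out[ok] = np.log10(a[ok] / b[ok])
    return out


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Median discrete-gamma category rates (mean 1) for shape parameter a."""
    if n_categories == 1:
        return np.array([1.0])
    qs = (2.0 * np.arange(n_categories) + 1.0) / (2.0 * n_categories)
    rates = gamma_dist.ppf(qs, a=shape, scale=1.0 / shape)
    return rates / rates.mean()


def mixture_categories(shape: float, n_gamma: int, p_inv: float = 0.0) -> list:
    """Invariant + discrete-gamma mixture with overall mean rate 1."""
    cats = []
    if p_inv > 0:
        cats.append((0.0, p_inv))
    g = discrete_gamma_rates(shape, n_gamma) / max(1.0 - p_inv, 1e-12)
    cats.extend((float(r), (1.0 - p_inv) / n_gamma) for r in g)
    return cats


# ---------------------------------------------------------------------------
# pruning likelihood


def _encode_patterns(rows: list[str], states: str | list[str]):
    """Compress alignment columns into unique patterns with counts.

    Unknown symbols and gaps encode as -1 (uninformative: partial
    likelihood of ones).  Returns (patterns [n_seq x n_pat], counts,
    column_pattern index per column).
    """
    index = {s: i for i, s in enumerate(states)}
    mat = np.array(
        [[index.get(c, -1) for c in row] for row in rows], dtype=np.int16
    )
    cols = [tuple(mat[:, j]) for j in range(mat.shape[1])]
    uniq: dict[tuple, int] = {}
    col_to_pat = np.empty(len(cols), dtype=int)
    for j, c in enumerate(cols):
        if c not in uniq:
            uniq[c] = len(uniq)
        col_to_pat[j] = uniq[c]
    patterns = np.array(list(uniq.keys()), dtype=np.int16).T
    counts = np.bincount(col_to_pat, minlength=len(uniq)).astype(float)
    return patterns, counts, col_to_pat


def _category_site_logliks(
    tree: PhyloTree,
    species: list[str],
    patterns: np.ndarray,
    pi: np.ndarray,
    Q: np.ndarray,
    rate: float,
    scale: float,
    extra_pattern: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pattern log likelihood under one rate category (pruning).

    ``patterns`` is (n_species, n_patterns) of state indices (-1 = gap).
    """
    k = len(pi)
    sp_index = {sp: i for i, sp in enumerate(species)}
    if extra_pattern is not None:
        patterns = np.concatenate([patterns, extra_pattern[:, None]], axis=1)
    npat = patterns.shape[1]
    eye = np.eye(k)

    def visit(node):
        # returns (partial [k x npat], log scaling [npat])
        if node.is_tip:
            i = sp_index[node.label]
            idx = patterns[i]
            part = np.where(idx[None, :] >= 0, eye[:, np.clip(idx, 0, k - 1)], 1.0)
            return part, np.zeros(npat)
        part = np.ones((k, npat))
        logs = np.zeros(npat)
        for child in node.children:
            cpart, clog = visit(child)
            t = child.length * scale * rate
            P = expm(Q * t) if t > 0 else eye
            part = part * (P @ cpart)
            logs = logs + clog
        mx = part.max(axis=0)
        safe = np.where(mx > 0, mx, 1.0)
        return part / safe, logs + np.where(mx > 0, np.log(safe), -np.inf)

    part, logs = visit(tree.root)
    lik = pi @ part
    with np.errstate(divide="ignore"):
        return np.log(lik) + logs


def pruning_loglik(
    tree: PhyloTree,
    species: list[str],
    patterns: np.ndarray,
    counts: np.ndarray,
    model: ReversibleModel,
    scale: float = 1.0,
    ascertainment: str | None = None,
) -> tuple[float, np.ndarray]:
    """Mixture log likelihood over patterns; returns (total, per-pattern
    per-category log liks [n_cat x n_pat]).

    ``ascertainment='variable'`` conditions each column on not being the
    all-absent (state-0) pattern, the correction used for gap characters.
    """
    Q = rate_matrix(model)
    pi = model.freqs
    extra = None
    if ascertainment == "variable":
        extra = np.zeros(patterns.shape[0], dtype=np.int16)  # the all-0 pattern
    cat_logs = []
    for rate, _ in model.rate_categories:
        cat_logs.append(
            _category_site_logliks(tree, species, patterns, pi, Q, rate, scale, extra)
        )
    cat_logs = np.array(cat_logs)
    logw = np.log(np.array([w for _, w in model.rate_categories]))
    site_log = logsumexp(cat_logs + logw[:, None], axis=0)
    if extra is not None:
        log_p0 = site_log[-1]
        site_log = site_log[:-1]
        cat_logs = cat_logs[:, :-1]
        # conditional likelihood: divide every column by (1 - P(all absent))
        site_log = site_log - np.log1p(-np.exp(min(log_p0, -1e-12)))
    total = float(site_log @ counts)
    return total, cat_logs


# ---------------------------------------------------------------------------
# meta-alignments and model fitting


def sample_meta_alignment(
    regions: list[Region],
    alignments: dict[str, ScoredAlignment],
    n_columns: int,
    max_gap_fraction: float,
    seed: int,
) -> ScoredAlignment:
    """Uniform without-replacement sample of region columns.

    A column is eligible if its gap fraction (over its own alignment's
    rows) is strictly below ``max_gap_fraction``.  The meta-alignment's
    species set is the union over source alignments; species absent from a
    column's source alignment appear as gaps.
    """
    pool = []  # (alignment_id, column)
    for region in regions:
        aln = alignments[region.alignment_id]
        gap = aln.gap_matrix()
        frac = gap[:, region.start : region.stop].mean(axis=0)
        for off in np.nonzero(frac < max_gap_fraction)[0]:
            pool.append((region.alignment_id, region.start + int(off)))
    if len(pool) < n_columns:
        raise ValueError(
            f"only {len(pool)} eligible columns for a request of {n_columns}"
        )
    rng = np.random.default_rng(seed)
    chosen = [pool[i] for i in rng.choice(len(pool), size=n_columns, replace=False)]
    species = sorted({sp for aid, _ in chosen for sp in alignments[aid].species})
    sp_index = {sp: i for i, sp in enumerate(species)}
    cols = np.full((len(species), n_columns), GAP, dtype="U1")
    for j, (aid, col) in enumerate(chosen):
        aln = alignments[aid]
        for i, sp in enumerate(aln.species):
            cols[sp_index[sp], j] = aln.rows[i][col]
    rows = ["".join(cols[i]) for i in range(len(species))]
    return ScoredAlignment("meta", species, rows)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def fit_reversible_model(
    meta_alignment: ScoredAlignment,
    tree: PhyloTree,
    n_categories: int = 4,
    states: str = STANDARD_AA,
    optimize_freqs: bool = True,
    n_restarts: int = 3,
    seed: int = 0,
) -> tuple[ReversibleModel, float, float]:
    """ML fit of a reversible model with discrete-gamma rate categories.

    The branch lengths are a single multiplicative scale of ``tree`` (the
    reference topology is kept; only its overall length is free), which is
    the restriction used throughout the per-alignment fits.  Returns
    (model, scale, loglik); the model's mean rate is 1 by construction, so
    ``scale`` carries all divergence.
    """
    species = meta_alignment.species
    missing = set(species) - set(tree.tip_labels)
    if missing:
        raise KeyError(f"species not on tree: {sorted(missing)}")
    if len(set(tree.tip_labels) - set(species)):
        tree = prune_to_species(tree, species)
    if len(species) < 2:
        raise ValueError("need at least 2 sequences")
    patterns, counts, _ = _encode_patterns(meta_alignment.rows, states)
    k = len(states)
    m = k * (k - 1) // 2
    iu = np.triu_indices(k, 1)
    emp = np.ones(k)
    for row in meta_alignment.rows:
        for c in row:
            if c in states:
                emp[states.index(c)] += 1
    emp = emp / emp.sum()

    def unpack(theta):
        s = np.ones(m)
        s[1:] = np.exp(theta[: m - 1])
        S = np.zeros((k, k))
        S[iu] = s
        S = S + S.T
        off = m - 1
        if optimize_freqs:
            pi = _softmax(np.concatenate([[0.0], theta[off : off + k - 1]]))
            off += k - 1
        else:
            pi = emp
        scale = np.exp(theta[off])
        shape = np.exp(theta[off + 1]) if n_categories > 1 else 1.0
        cats = [(float(r), 1.0 / n_categories) for r in discrete_gamma_rates(shape, n_categories)]
        return ReversibleModel(states, pi, S, cats), scale

    def nll(theta):
        try:
            model, scale = unpack(theta)
            ll, _ = pruning_loglik(tree, species, patterns, counts, model, scale)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    n_par = (m - 1) + (k - 1 if optimize_freqs else 0) + 1 + (1 if n_categories > 1 else 0)
    rng = np.random.default_rng(seed)
    x0 = np.zeros(n_par)
    off = m - 1 + (k - 1 if optimize_freqs else 0)
    x0[off] = np.log(0.5)  # starting branch scale
    best = None
    bounds = [(-13.0, 13.0)] * n_par
    bounds[off] = (np.log(1e-8), np.log(1e3))
    for r in range(max(1, n_restarts)):
        start = x0 if r == 0 else x0 + rng.normal(0, 0.5, size=n_par)
        res = minimize(nll, start, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("model fit did not converge; no finite likelihood found")
    model, scale = unpack(best.x)
    return model, float(scale), float(-best.fun)


def fit_branch_scale_and_site_rates(
    aln: ScoredAlignment,
    model: ReversibleModel,
    reference_tree: PhyloTree,
    n_gamma: int = 4,
    use_invariant: bool = True,
    columns: np.ndarray | None = None,
) -> tuple[float, np.ndarray, float]:
    """Fit the branch scale of the reference tree under a fixed model.

    The exchangeabilities and frequencies stay fixed; the free parameters
    are the tree scale, the gamma shape, and (optionally) the invariant
    proportion.  Returns (scale, per-column posterior-mean rates, loglik);
    all-gap columns get NaN rates.
    """
    species = aln.species
    tree = reference_tree
    if set(tree.tip_labels) - set(species):
        tree = prune_to_species(tree, [sp for sp in tree.tip_labels if sp in set(species)])
    rows = aln.rows
    if columns is not None:
        rows = ["".join(r[j] for j in columns) for r in rows]
    states = model.states
    patterns, counts, col_to_pat = _encode_patterns(rows, states)
    all_gap = np.all(patterns == -1, axis=0)

    def build(theta):
        scale = np.exp(theta[0])
        shape = np.exp(theta[1])
        p_inv = 1.0 / (1.0 + np.exp(-theta[2])) if use_invariant else 0.0
        cats = mixture_categories(shape, n_gamma, p_inv)
        return ReversibleModel(states, model.freqs, model.exchangeabilities, cats), scale

    def nll(theta):
        mdl, scale = build(theta)
        ll, _ = pruning_loglik(tree, species, patterns, counts, mdl, scale)
        return -ll if np.isfinite(ll) else 1e12

    x0 = np.array([np.log(0.5), 0.0, -2.0][: 3 if use_invariant else 2])
    bounds = [(np.log(1e-8), np.log(1e3)), (np.log(0.05), np.log(50.0))]
    if use_invariant:
        bounds.append((-8.0, 8.0))
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
    mdl, scale = build(res.x)
    _, cat_logs = pruning_loglik(tree, species, patterns, counts, mdl, scale)
    rates = np.array([r for r, _ in mdl.rate_categories])
    logw = np.log([w for _, w in mdl.rate_categories])
    post = np.exp(cat_logs + logw[:, None] - logsumexp(cat_logs + logw[:, None], axis=0))
    pattern_rate = rates @ post
    pattern_rate[all_gap] = np.nan
    col_rates = pattern_rate[col_to_pat]
    return float(scale), col_rates, float(-res.fun)


def region_average_aa_rate(
    column_rates: np.ndarray,
    scale: float,
    fitted_tree_length: float,
    pruned_reference_length: float,
    region: Region,
) -> float:
    """Region rate = mean over region columns of (factor x column rate).

    The normalization factor is the fitted tree length over the pruned
    reference tree length, which removes the species-sampling contribution
    to total branch length.
    """
    if pruned_reference_length <= 0:
        raise ValueError("pruned reference tree length must be > 0")
    factor = fitted_tree_length / pruned_reference_length
    window = np.asarray(column_rates[region.start : region.stop], dtype=float)
    window = window[np.isfinite(window)]
    if window.size == 0:
        return float("nan")
    return float(np.mean(factor * window))


# ---------------------------------------------------------------------------
# indel characters


def encode_indel_characters(aln: ScoredAlignment) -> IndelCharacterAlignment:
    """Binary gap-run characters with the nesting-aware coding rule.

    Characters are the unique (start, stop) intervals of maximal gap runs
    over all sequences; a sequence is coded 1 for a character if it carries
    exactly that run, or the character lies strictly inside one of its
    longer runs.
    """
    runs_by_row = []
    all_runs = set()
    gap = aln.gap_matrix()
    for i in range(aln.n_species):
        runs = []
        j = 0
        n = aln.n_columns
        while j < n:
            if gap[i, j]:
                start = j
                while j < n and gap[i, j]:
                    j += 1
                runs.append((start, j))
            else:
                j += 1
        runs_by_row.append(runs)
        all_runs.update(runs)
    characters = sorted(all_runs)
    coding = np.zeros((aln.n_species, len(characters)), dtype=np.int8)
    for i, runs in enumerate(runs_by_row):
        runset = set(runs)
        for c, (cs, ce) in enumerate(characters):
            if (cs, ce) in runset:
                coding[i, c] = 1
            else:
                for rs, re_ in runs:
                    if rs <= cs and ce <= re_ and (re_ - rs) > (ce - cs):
                        coding[i, c] = 1
                        break
    return IndelCharacterAlignment(characters, list(aln.species), coding)


def fit_indel_rates(
    chars: IndelCharacterAlignment,
    reference_tree: PhyloTree,
    min_characters: int = 5,
    exclude_all_present: bool = False,
) -> tuple[dict, float, np.ndarray]:
    """Two-state rates for gap-run characters, mapped back onto columns.

    Fits a binary reversible model (free stationary frequency, branch
    scale on the pruned reference tree, one discrete-gamma category per
    five characters up to four) with a conditional likelihood correcting
    for the unobservable all-absent pattern.  Per-character posterior-mean
    rates are normalized by the fitted/reference tree-length factor and
    each split half onto the character's start column and half onto its
    stop - 1 column.  With fewer than ``min_characters`` characters every
    rate is zero.

    Returns (column rate map, scale, per-character rates).
    """
    n_chars = len(chars.characters)
    col_rates: dict[int, float] = {}
    if n_chars == 0:
        return col_rates, 0.0, np.zeros(0)
    if n_chars < min_characters:
        char_rates = np.zeros(n_chars)
        for (cs, ce) in chars.characters:
            col_rates[cs] = col_rates.get(cs, 0.0)
            col_rates[ce - 1] = col_rates.get(ce - 1, 0.0)
        return col_rates, 0.0, char_rates
    species = chars.species
    tree = reference_tree
    if set(tree.tip_labels) - set(species):
        tree = prune_to_species(tree, [sp for sp in tree.tip_labels if sp in set(species)])
    rows = ["".join("1" if v else "0" for v in chars.coding[i]) for i in range(len(species))]
    patterns, counts, col_to_pat = _encode_patterns(rows, "01")
    n_gamma = min(4, max(1, n_chars // 5))
    asc = "variable"

    def build(theta):
        f = 1.0 / (1.0 + np.exp(-theta[0]))
        pi = np.array([1.0 - f, f])
        S = np.array([[0.0, 1.0], [1.0, 0.0]])
        shape = np.exp(theta[1]) if n_gamma > 1 else 1.0
        cats = [(float(r), 1.0 / n_gamma) for r in discrete_gamma_rates(shape, n_gamma)]
        scale = np.exp(theta[2])
        return ReversibleModel("01", pi, S, cats), scale

    def nll(theta):
        mdl, scale = build(theta)
        ll, _ = pruning_loglik(
            tree, species, patterns, counts, mdl, scale, ascertainment=asc
        )
        return -ll if np.isfinite(ll) else 1e12

    x0 = np.array([0.0, 0.0, np.log(0.3)])
    bounds = [(-8.0, 8.0), (np.log(0.05), np.log(50.0)), (np.log(1e-8), np.log(1e3))]
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
    mdl, scale = build(res.x)
    _, cat_logs = pruning_loglik(
        tree, species, patterns, counts, mdl, scale, ascertainment=asc
    )
    rates = np.array([r for r, _ in mdl.rate_categories])
    logw = np.log([w for _, w in mdl.rate_categories])
    post = np.exp(cat_logs + logw[:, None] - logsumexp(cat_logs + logw[:, None], axis=0))
    pattern_rate = rates @ post
    char_rel = pattern_rate[col_to_pat]
    # tree-length normalization factor, as for amino-acid rates
    ref_len = tree.total_length()
    factor = (scale * ref_len) / ref_len if ref_len > 0 else 0.0
    char_rates = char_rel * factor
    for (cs, ce), rate in zip(chars.characters, char_rates):
        col_rates[cs] = col_rates.get(cs, 0.0) + 0.5 * float(rate)
        col_rates[ce - 1] = col_rates.get(ce - 1, 0.0) + 0.5 * float(rate)
    return col_rates, float(scale), char_rates


# ---------------------------------------------------------------------------
# partitioning


def partition_alignment(
    aln: ScoredAlignment,
    disorder_regions: list[Region],
    min_sequences: int = 20,
    min_nongap: int = 30,
) -> dict[str, np.ndarray]:
    """Split columns into disorder/order partitions with fallback rules.

    A partition is created only if at least ``min_sequences`` sequences
    have at least ``min_nongap`` non-gap symbols within it; a failing
    partition is consolidated into the passing one; if neither passes, the
    alignment is skipped (empty dict).
    """
    ncol = aln.n_columns
    in_disorder = np.zeros(ncol, dtype=bool)
    for region in disorder_regions:
        in_disorder[region.start : region.stop] = True
    gap = aln.gap_matrix()

    def passes(mask: np.ndarray) -> bool:
        if not mask.any():
            return False
        nongap = (~gap[:, mask]).sum(axis=1)
        return int((nongap >= min_nongap).sum()) >= min_sequences

    cols = np.arange(ncol)
    d_ok, o_ok = passes(in_disorder), passes(~in_disorder)
    if d_ok and o_ok:
        return {"disorder": cols[in_disorder], "order": cols[~in_disorder]}
    if d_ok:
        return {"disorder": cols}
    if o_ok:
        return {"order": cols}
    return {}
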