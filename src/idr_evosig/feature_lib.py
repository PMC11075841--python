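"""Molecular features of disordered protein segments.

Computes the canonical 82-component feature vector for an ungapped segment:
per-residue and class composition fractions, homo-repeat counts, charge
patterning statistics (SCD, kappa, omega), physicochemical summaries
(hydropathy, isoelectric point, PPII propensity, Wootton-Federhen
complexity), a radius-of-gyration length proxy, and short-linear-motif
counts.  The registry is declarative (``data/features.tsv``) so the set can
be inspected, altered, or round-tripped without touching code.

Charge convention: D/E carry -1, K/R carry +1, histidine is neutral (the
standard choice for kappa/SCD near pH 7); configurable via ``CHARGES``.
Motif counts are left as raw counts, never normalized by length.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "FeatureDef",
    "FeatureVector",
    "load_registry",
    "dump_registry",
    "default_registry",
    "compute_feature_vector",
    "composition_fraction",
    "repeat_count",
    "motif_count",
    "scd",
    "kappa",
    "omega",
    "wf_complexity",
    "isoelectric_point",
    "net_charge",
    "hydropathy",
    "ppii_propensity",
    "rg_excluded_volume",
    "disorder_fraction",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

CHARGES = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}  # His neutral by default

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

# per-residue polyproline-II propensities (Elam/Hilser experimental scale)
PPII_SCALE = {
    "A": 0.37, "C": 0.25, "D": 0.30, "E": 0.42, "F": 0.17, "G": 0.13,
    "H": 0.20, "I": 0.39, "K": 0.56, "L": 0.24, "M": 0.36, "N": 0.27,
    "P": 1.00, "Q": 0.53, "R": 0.38, "S": 0.24, "T": 0.32, "V": 0.39,
    "W": 0.25, "Y": 0.25,
}

# EMBOSS pKa values; positive groups first, then negative
PKA_POSITIVE = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


def _check(seq: str) -> str:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(STANDARD_AA)
    if bad:
        raise ValueError(f"non-standard residues {sorted(bad)}")
    return seq


# ---------------------------------------------------------------------------
# elementary statistics


def composition_fraction(seq: str, char_class: str) -> float:
    """Fraction of residues belonging to ``char_class``, in [0, 1]."""
    _check(seq)
    members = set(char_class)
    return sum(1 for c in seq if c in members) / len(seq)


def repeat_count(seq: str, char_class: str) -> int:
    """Number of maximal runs of >= 2 consecutive class members."""
    _check(seq)
    return len(re.findall(f"[{char_class}]{{2,}}", seq))


def motif_count(seq: str, motif_regex: str | re.Pattern) -> int:
    """Non-overlapping, left-to-right greedy match count (raw count)."""
    _check(seq)
    return len(re.findall(motif_regex, seq))


def net_charge(seq: str) -> float:
    _check(seq)
    return sum(CHARGES.get(c, 0.0) for c in seq)


def hydropathy(seq: str) -> float:
    _check(seq)
    return sum(KYTE_DOOLITTLE[c] for c in seq) / len(seq)


def ppii_propensity(seq: str) -> float:
    _check(seq)
    return sum(PPII_SCALE[c] for c in seq) / len(seq)


def rg_excluded_volume(n_residues: int) -> float:
    """Length proxy N**nu with the excluded-volume exponent nu = 0.598."""
    if n_residues < 1:
        raise ValueError("need n >= 1")
    return float(n_residues) ** 0.598


def disorder_fraction(scores, threshold: float = 0.5) -> float:
    """Fraction of residues whose disorder score is >= ``threshold``."""
    scores = np.asarray(scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    if scores.size == 0:
        return float("nan")
    return float(np.mean(scores >= threshold))


def wf_complexity(seq: str) -> float:
    """Wootton-Federhen K1 = (1/L) * log_20(L! / prod_a n_a!); 0 for homopolymers."""
    _check(seq)
    L = len(seq)
    counts = [seq.count(a) for a in set(seq)]
    log_mult = math.lgamma(L + 1) - sum(math.lgamma(n + 1) for n in counts)
    return log_mult / (L * math.log(20.0))


def scd(seq: str) -> float:
    """Sequence charge decoration: (1/N) * sum_{i<j} q_i q_j * sqrt(j - i)."""
    _check(seq)
    q = np.array([CHARGES.get(c, 0.0) for c in seq])
    idx = np.nonzero(q)[0]
    if idx.size < 2:
        return 0.0
    qi = q[idx]
    sep = np.sqrt(np.abs(idx[:, None] - idx[None, :]).astype(float))
    total = (qi[:, None] * qi[None, :] * sep).sum() / 2.0
    return float(total / len(seq))


def _sigma(f1: float, f2: float) -> float:
    tot = f1 + f2
    return (f1 - f2) ** 2 / tot if tot > 0 else 0.0


def _delta(labels: np.ndarray, windows=(5, 6)) -> float:
    """Mean squared deviation of blob charge asymmetry from the global value.

    ``labels`` holds +1/-1/0 class assignments; overlapping sliding blobs.
    """
    n = len(labels)
    f1 = float(np.mean(labels > 0))
    f2 = float(np.mean(labels < 0))
    sig_seq = _sigma(f1, f2)
    deltas = []
    for g in windows:
        if n < g:
            continue
        pos = np.convolve((labels > 0).astype(float), np.ones(g), "valid") / g
        neg = np.convolve((labels < 0).astype(float), np.ones(g), "valid") / g
        sig = np.where(pos + neg > 0, (pos - neg) ** 2 / np.where(pos + neg > 0, pos + neg, 1.0), 0.0)
        deltas.append(float(np.mean((sig - sig_seq) ** 2)))
    if not deltas:
        return float("nan")
    return float(np.mean(deltas))


def _patterning(labels: np.ndarray) -> float:
    """kappa-style normalized patterning for a +1/-1/0 label vector."""
    n_pos = int(np.sum(labels > 0))
    n_neg = int(np.sum(labels < 0))
    n_neu = int(np.sum(labels == 0))
    if n_pos + n_neg < 2 or len(labels) < 5:
        return float("nan")
    delta = _delta(labels)
    # maximally segregated arrangements of the same composition
    candidates = [
        [1] * n_pos + [0] * n_neu + [-1] * n_neg,
        [1] * n_pos + [-1] * n_neg + [0] * n_neu,
        [0] * n_neu + [1] * n_pos + [-1] * n_neg,
    ]
    dmax = max(_delta(np.array(c, dtype=float)) for c in candidates)
    if not np.isfinite(delta) or not np.isfinite(dmax) or dmax <= 0:
        return float("nan")
    return float(min(delta / dmax, 1.0))


def kappa(seq: str) -> float:
    """Das-Pappu charge patterning in [0, 1]; NaN when undefined.

    0 for well-mixed charges, 1 for fully segregated blocks; undefined for
    sequences shorter than the blob or with fewer than two charged residues.
    """
    _check(seq)
    labels = np.array([CHARGES.get(c, 0.0) for c in seq])
    return _patterning(labels)


def omega(seq: str) -> float:
    """Patterning of {D,E,K,R,P} against all other residues, in [0, 1]."""
    _check(seq)
    group = set("DEKRP")
    labels = np.array([1.0 if c in group else -1.0 for c in seq])
    return _patterning(labels)


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH at which the Henderson-Hasselbalch net charge crosses zero.

    Bisection on (0, 14); net charge is monotone decreasing in pH, so the
    crossing is unique.  Terminal groups are included.
    """
    _check(seq)

    def charge(ph: float) -> float:
        pos = sum(
            (seq.count(res) if res != "Nterm" else 1) / (1.0 + 10.0 ** (ph - pka))
            for res, pka in PKA_POSITIVE.items()
        )
        neg = sum(
            (seq.count(res) if res != "Cterm" else 1) / (1.0 + 10.0 ** (pka - ph))
            for res, pka in PKA_NEGATIVE.items()
        )
        return pos - neg

    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if charge(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# registry


@dataclass(frozen=True)
class FeatureDef:
    name: str
    kind: str
    spec: str
    note: str = ""

    def __post_init__(self):
        if self.kind == "regex_count":
            re.compile(self.spec)  # invalid regex fails at load time


@dataclass
class FeatureVector:
    segment_id: str
    names: list[str]
    values: np.ndarray  # NaN marks missing (undefined), never silently zero


_KINDS = {
    "composition_fraction",
    "regex_count",
    "repeat",
    "physicochemical",
    "patterning",
    "length_derived",
}

_BUILTINS = {
    "hydropathy": hydropathy,
    "isoelectric_point": isoelectric_point,
    "net_charge": net_charge,
    "ncpr": lambda s: net_charge(s) / len(s),
    "ppii_propensity": ppii_propensity,
    "wf_complexity": wf_complexity,
    "scd": scd,
    "kappa": kappa,
    "omega": omega,
}


def load_registry(path=None) -> list[FeatureDef]:
    """Load a feature registry TSV; the packaged default has 82 entries."""
    if path is None:
        source = resources.files("idr_evosig").joinpath("data/features.tsv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    defs: list[FeatureDef] = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("name\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed registry line: {line!r}")
        name, kind, spec = parts[:3]
        note = parts[3] if len(parts) > 3 else ""
        if kind not in _KINDS:
            raise ValueError(f"unknown feature kind {kind!r} for {name}")
        defs.append(FeatureDef(name, kind, spec, note))
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names in registry")
    return defs


def dump_registry(defs: list[FeatureDef], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tkind\tspec\tnote\n")
        for d in defs:
            fh.write(f"{d.name}\t{d.kind}\t{d.spec}\t{d.note}\n")


_DEFAULT: list[FeatureDef] | None = None


def default_registry() -> list[FeatureDef]:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_registry()
        assert len(_DEFAULT) == 82
    return _DEFAULT


def _evaluate(d: FeatureDef, seq: str, scores) -> float:
    if d.kind == "composition_fraction":
        return composition_fraction(seq, d.spec)
    if d.kind == "repeat":
        return float(repeat_count(seq, d.spec))
    if d.kind == "regex_count":
        return float(motif_count(seq, d.spec))
    if d.kind == "length_derived":
        return float(len(seq)) ** float(d.spec)
    if d.kind in ("physicochemical", "patterning"):
        if d.spec == "disorder_fraction":
            return disorder_fraction(scores) if scores is not None else float("nan")
        fn = _BUILTINS.get(d.spec)
        if fn is None:
            raise KeyError(f"unknown builtin feature function {d.spec!r}")
        return float(fn(seq))
    raise KeyError(f"unknown feature kind {d.kind!r}")


def compute_feature_vector(
    segment: str,
    registry: list[FeatureDef] | None = None,
    scores=None,
    segment_id: str = "",
) -> FeatureVector:
    """Evaluate every registry entry on an ungapped standard-residue segment.

    ``scores`` (optional) are the per-residue disorder scores of the segment,
    used only by score-derived entries; undefined values come back as NaN.
    """
    registry = registry if registry is not None else default_registry()
    _check(segment)
    values = np.array([_evaluate(d, segment, scores) for d in registry])
    return FeatureVector(segment_id, [d.name for d in registry], values)
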