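"""Calling disorder and order regions from aligned disorder-score traces.

Per-species scores are averaged column-wise with tree-derived sequence
weights (the Gaussian-process / Brownian-motion derivation: weights are the
normalized row sums of the inverse BM covariance, so redundant close
relatives share weight).  The averaged profile is thresholded with a dual
cutoff: a >0.6 mask supplies "seed" runs of at least 10 columns and a
dilated >0.4 mask supplies the extent to which seeds are expanded.  Order
regions are the exact complement.  Regions are then filtered on segment
quality (standard residues, missingness, >= 30 non-gap residues) and
phylogenetic diversity.

Coordinates are 0-based, half-open column intervals throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation

from .alignment import STANDARD_AA, GAP, ScoredAlignment
from .config import PipelineConfig
from .tree import PhyloTree, prune_to_species

__all__ = [
    "ColumnScoreProfile",
    "Region",
    "Segment",
    "gaussian_process_weights",
    "column_average_scores",
    "call_disorder_regions",
    "complement_order_regions",
    "extract_segments",
    "filter_regions",
]


@dataclass
class ColumnScoreProfile:
    alignment_id: str
    values: np.ndarray  # per-column weighted mean score, in [0, 1]
    support: np.ndarray  # per-column count of contributing species


@dataclass
class Segment:
    species: str
    sequence: str  # ungapped residues within the region's columns
    columns: np.ndarray  # alignment column of each residue
    scores: np.ndarray | None = None  # per-residue disorder scores


@dataclass
class Region:
    alignment_id: str
    start: int
    stop: int
    is_disorder: bool
    segments: dict = field(default_factory=dict)  # species -> Segment

    def __post_init__(self):
        if not (0 <= self.start < self.stop):
            raise ValueError(f"bad interval [{self.start}, {self.stop})")

    @property
    def region_id(self) -> str:
        kind = "D" if self.is_disorder else "O"
        return f"{self.alignment_id}:{self.start}-{self.stop}:{kind}"

    @property
    def n_species(self) -> int:
        return len(self.segments)


def gaussian_process_weights(
    tree: PhyloTree, present_species, mode: str = "renormalize"
) -> dict[str, float]:
    """Tree-based sequence weights: normalized row sums of the inverse
    Brownian-motion covariance.

    With species absent from an alignment, ``mode='renormalize'`` (the
    default) rescales the full-tree weights of the remaining species;
    ``mode='reprune'`` recomputes weights from the pruned tree.
    """
    present = [sp for sp in tree.tip_labels if sp in set(present_species)]
    if not present:
        raise ValueError("no present species on the tree")
    unknown = set(present_species) - set(tree.tip_labels)
    if unknown:
        raise KeyError(f"species not on tree: {sorted(unknown)}")
    if len(present) == 1:
        return {present[0]: 1.0}
    if mode == "reprune" and len(present) < tree.n_tips:
        tree = prune_to_species(tree, present)
        return gaussian_process_weights(tree, present, mode="renormalize")
    if mode not in ("renormalize", "reprune"):
        raise ValueError(f"unknown mode {mode!r}")
    order = tree.tip_labels
    C = tree.cov_matrix(order)
    try:
        raw = np.linalg.solve(C, np.ones(len(order)))
    except np.linalg.LinAlgError:
        raise ValueError("singular BM covariance (duplicate zero-distance tips?)")
    if np.any(raw < -1e-9):
        raw = np.clip(raw, 0.0, None)
    w = dict(zip(order, raw))
    total = sum(w[sp] for sp in present)
    if total <= 0:
        raise ValueError("degenerate weights: non-positive total")
    return {sp: w[sp] / total for sp in present}


def column_average_scores(
    aln: ScoredAlignment, tree: PhyloTree, mode: str = "renormalize"
) -> ColumnScoreProfile:
    """Tree-weighted per-column average of the aligned disorder scores.

    A species contributes at a column only where its residue is non-gap,
    not masked as missing, inside its own first..last non-gap span, and
    scored.  Columns with no contributor are filled by linear interpolation
    between the nearest scored columns (flat extrapolation at the ends).
    """
    if aln.scores is None:
        raise ValueError(f"{aln.alignment_id}: alignment has no scores")
    weights = gaussian_process_weights(tree, aln.species, mode=mode)
    wvec = np.array([weights[sp] for sp in aln.species])
    ncol = aln.n_columns
    gap = aln.gap_matrix()
    ok = ~gap & np.isfinite(aln.scores)
    # restrict to each sequence's own span
    for i in range(aln.n_species):
        nz = np.nonzero(~gap[i])[0]
        if nz.size:
            ok[i, : nz[0]] = False
            ok[i, nz[-1] + 1 :] = False
        else:
            ok[i, :] = False
    if aln.missing_mask is not None:
        ok &= ~aln.missing_mask
    wmat = np.where(ok, wvec[:, None], 0.0)
    totals = wmat.sum(axis=0)
    support = ok.sum(axis=0)
    values = np.full(ncol, np.nan)
    scored = totals > 0
    if not scored.any():
        raise ValueError(f"{aln.alignment_id}: no scored columns")
    vals = np.where(ok, np.nan_to_num(aln.scores), 0.0)
    values[scored] = (wmat * vals).sum(axis=0)[scored] / totals[scored]
    if (~scored).any():
        idx = np.nonzero(scored)[0]
        values = np.interp(np.arange(ncol), idx, values[idx])
    return ColumnScoreProfile(aln.alignment_id, values, support)


def _runs(mask: np.ndarray):
    """Maximal runs of True as (start, stop) half-open pairs."""
    out = []
    n = len(mask)
    j = 0
    while j < n:
        if mask[j]:
            start = j
            while j < n and mask[j]:
                j += 1
            out.append((start, j))
        else:
            j += 1
    return out


def call_disorder_regions(profile: ColumnScoreProfile, config: PipelineConfig) -> list[Region]:
    """Dual-cutoff disorder region calls (strict inequality at both cutoffs).

    Seeds are runs of >= ``seed_min_run`` columns above the high cutoff;
    each seed expands left and right through the binary-dilated low-cutoff
    mask; overlapping expansions merge.
    """
    values = np.asarray(profile.values, dtype=float)
    high = values > config.score_high_cutoff
    low = values > config.score_low_cutoff
    struct = np.ones(config.dilation_size, dtype=bool)
    low_dilated = binary_dilation(low, structure=struct)
    intervals = []
    low_runs = _runs(low_dilated)
    for start, stop in _runs(high):
        if stop - start < config.seed_min_run:
            continue
        enclosing = next((s, e) for s, e in low_runs if s <= start and stop <= e)
        intervals.append(enclosing)
    merged: list[list[int]] = []
    for start, stop in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], stop)
        else:
            merged.append([start, stop])
    return [Region(profile.alignment_id, s, e, True) for s, e in merged]


def complement_order_regions(disorder: list[Region], alignment_length: int, alignment_id: str | None = None) -> list[Region]:
    """Order regions exactly tile the complement of the disorder regions."""
    regions = sorted(disorder, key=lambda r: r.start)
    for a, b in zip(regions, regions[1:]):
        if b.start < a.stop:
            raise ValueError(f"overlapping disorder regions {a.region_id} and {b.region_id}")
    if regions and alignment_id is None:
        alignment_id = regions[0].alignment_id
    out = []
    cursor = 0
    for r in regions:
        if r.start > cursor:
            out.append(Region(r.alignment_id, cursor, r.start, False))
        cursor = r.stop
    if cursor < alignment_length:
        out.append(Region(alignment_id or "", cursor, alignment_length, False))
    return out


def extract_segments(region: Region, aln: ScoredAlignment) -> Region:
    """Populate a region's per-species ungapped segments (with scores)."""
    gap = aln.gap_matrix()
    for i, sp in enumerate(aln.species):
        cols = np.nonzero(~gap[i, region.start : region.stop])[0] + region.start
        if cols.size == 0:
            continue
        seq = "".join(aln.rows[i][j] for j in cols)
        scores = aln.scores[i, cols] if aln.scores is not None else None
        region.segments[sp] = Segment(sp, seq, cols, scores)
    return region


def filter_regions(
    regions: list[Region], config: PipelineConfig, aln: ScoredAlignment | None = None
) -> tuple[list[Region], dict]:
    """Apply segment-level and region-level filters; report per-filter counts.

    Segment drops: non-standard residues, overlap with the missing mask,
    fewer than ``min_nongap_length`` non-gap residues.  Region drops:
    surviving segments fail the diversity criteria (default: at least
    ``min_segments`` segments and, when clade groups are configured,
    representatives from at least ``min_clades`` of them).
    """
    crit = config.diversity_criteria
    min_segments = int(crit.get("min_segments", 20))
    min_clades = int(crit.get("min_clades", 2))
    clades = crit.get("clades")
    counts = {
        "segments_nonstandard": 0,
        "segments_missing_overlap": 0,
        "segments_short": 0,
        "regions_in": len(regions),
        "regions_failed_diversity": 0,
        "regions_kept": 0,
    }
    standard = set(STANDARD_AA)
    kept = []
    for region in regions:
        if aln is not None and not region.segments:
            extract_segments(region, aln)
        surviving = {}
        for sp, seg in region.segments.items():
            if set(seg.sequence) - standard:
                counts["segments_nonstandard"] += 1
                continue
            if aln is not None and aln.missing_mask is not None:
                i = aln.species.index(sp)
                if aln.missing_mask[i, seg.columns].any():
                    counts["segments_missing_overlap"] += 1
                    continue
            if len(seg.sequence) < config.min_nongap_length:
                counts["segments_short"] += 1
                continue
            surviving[sp] = seg
        ok = len(surviving) >= min_segments
        if ok and clades:
            present = set(surviving)
            n_rep = sum(1 for group in clades if present & set(group))
            ok = n_rep >= min_clades
        if ok:
            region.segments = surviving
            kept.append(region)
        else:
            counts["regions_failed_diversity"] += 1
    counts["regions_kept"] = len(kept)
    return kept, counts
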