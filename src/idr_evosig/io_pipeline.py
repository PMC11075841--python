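"""End-to-end pipeline: regions -> rates -> features -> trait fits ->
signatures -> clusters -> enrichment.

Datasets are directories of aligned FASTAs with score TSVs beside them and
one reference tree; every stage is also callable on its own.  All tables
are TSV, all randomness flows from the single config seed through
per-stage child seeds, and the run log records every filter count.
"""

from __future__ import annotations

import json
import os
from glob import glob

import numpy as np
import pandas as pd

from .alignment import ScoredAlignment, read_msa_fasta, read_score_tsv
from .config import PipelineConfig, derive_seed
from .feature_lib import compute_feature_vector, default_registry
from .region_calling import (
    Region,
    call_disorder_regions,
    column_average_scores,
    complement_order_regions,
    extract_segments,
    filter_regions,
)
from .signatures import Signature, cluster_signatures, filter_by_rates, significance_counts, zscore_normalize
from .subst_models import (
    ReversibleModel,
    encode_indel_characters,
    fit_branch_scale_and_site_rates,
    fit_indel_rates,
    partition_alignment,
    region_average_aa_rate,
)
from .trait_models import (
    calibrate_critical_values,
    fit_bm_many,
    fit_ou_many,
    score_rate_per_region,
)
from .tree import PhyloTree, prune_to_species, read_newick_tree
from .alignment import STANDARD_AA

__all__ = [
    "PipelineConfig",
    "ScoredAlignment",
    "PhyloTree",
    "read_msa_fasta",
    "read_newick_tree",
    "prune_to_species",
    "load_dataset",
    "run_pipeline",
]

DEFAULT_RATE_GRID = [10.0 ** (e / 2.0) for e in range(-6, 7)]  # 10^-3 .. 10^3


def load_dataset(dataset_dir):
    """Read tree.nwk plus every aligned FASTA (+ optional score TSV)."""
    tree_path = os.path.join(dataset_dir, "tree.nwk")
    if not os.path.exists(tree_path):
        raise FileNotFoundError(f"no tree.nwk in {dataset_dir}")
    tree = read_newick_tree(tree_path)
    alignments: dict[str, ScoredAlignment] = {}
    for fasta in sorted(glob(os.path.join(dataset_dir, "*.fasta"))):
        aln = read_msa_fasta(fasta)
        scores = fasta[: -len(".fasta")] + ".scores.tsv"
        if os.path.exists(scores):
            aln.scores = read_score_tsv(scores, aln)
        mask = fasta[: -len(".fasta")] + ".mask.tsv"
        if os.path.exists(mask):
            aln.missing_mask = np.loadtxt(mask, dtype=bool, delimiter="\t")
        alignments[aln.alignment_id] = aln
    if not alignments:
        raise ValueError(f"no alignments in {dataset_dir}")
    return tree, alignments


# ---------------------------------------------------------------------------
# stages


def stage_regions(alignments, tree, config):
    regions: list[Region] = []
    log = {}
    for aid, aln in sorted(alignments.items()):
        profile = column_average_scores(aln, tree)
        disorder = call_disorder_regions(profile, config)
        order = complement_order_regions(disorder, aln.n_columns, aid)
        called = disorder + order
        for r in called:
            extract_segments(r, aln)
        kept, counts = filter_regions(called, config, aln)
        regions.extend(kept)
        log[aid] = counts
    return regions, log


def _empirical_model(aln: ScoredAlignment, columns=None) -> ReversibleModel:
    """Uniform-exchangeability model with the partition's own frequencies."""
    counts = np.ones(len(STANDARD_AA))
    cols = set(map(int, columns)) if columns is not None else None
    for row in aln.rows:
        for j, c in enumerate(row):
            if (cols is None or j in cols) and c in STANDARD_AA:
                counts[STANDARD_AA.index(c)] += 1
    freqs = counts / counts.sum()
    S = np.ones((len(STANDARD_AA),) * 2)
    np.fill_diagonal(S, 0.0)
    return ReversibleModel(STANDARD_AA, freqs, S)


def stage_rates(alignments, tree, regions, config):
    """Per-region amino-acid and indel rates against the scaled reference tree."""
    by_aln: dict[str, list[Region]] = {}
    for r in regions:
        by_aln.setdefault(r.alignment_id, []).append(r)
    rows = []
    skipped = []
    for aid, regs in sorted(by_aln.items()):
        aln = alignments[aid]
        species = [sp for sp in tree.tip_labels if sp in set(aln.species)]
        pruned = prune_to_species(tree, species) if len(species) < tree.n_tips else tree
        ref_len = pruned.total_length()
        disorder = [r for r in regs if r.is_disorder]
        parts = partition_alignment(
            aln, disorder, min_sequences=min(config.diversity_criteria.get("min_segments", 20), aln.n_species),
            min_nongap=config.min_nongap_length,
        )
        if not parts:
            skipped.append(aid)
            continue
        col_rate = np.full(aln.n_columns, np.nan)
        col_factor = np.full(aln.n_columns, np.nan)
        for name, cols in parts.items():
            model = _empirical_model(aln, cols)
            scale, rates_part, _ = fit_branch_scale_and_site_rates(aln, model, pruned, columns=cols)
            col_rate[cols] = rates_part
            col_factor[cols] = scale  # fitted length / reference length
        indel_cols, _, _ = fit_indel_rates(encode_indel_characters(aln), pruned)
        indel_track = np.zeros(aln.n_columns)
        for col, rate in indel_cols.items():
            indel_track[col] += rate
        for r in regs:
            window = slice(r.start, r.stop)
            vals = col_rate[window] * col_factor[window]
            vals = vals[np.isfinite(vals)]
            aa_rate = float(vals.mean()) if vals.size else float("nan")
            indel_rate = float(indel_track[window].mean())
            scale = float(np.nanmean(col_factor[window]))
            # average disorder score rate on the tree, for the upper-decile set
            mean_scores = {
                sp: float(np.nanmean(seg.scores))
                for sp, seg in r.segments.items()
                if seg.scores is not None and np.isfinite(seg.scores).any()
            }
            if len(mean_scores) >= 3:
                sub = prune_to_species(pruned, list(mean_scores))
                score_rate = score_rate_per_region(sub, {k: mean_scores[k] for k in sub.tip_labels})
            else:
                score_rate = float("nan")
            rows.append(
                {
                    "region_id": r.region_id,
                    "alignment_id": aid,
                    "start": r.start,
                    "stop": r.stop,
                    "is_disorder": r.is_disorder,
                    "aa_rate": aa_rate,
                    "indel_rate": indel_rate,
                    "scale_factor": scale,
                    "score_rate": score_rate,
                }
            )
    return pd.DataFrame(rows), skipped


def stage_features(regions, registry=None):
    """82-feature vectors for every (region, species) segment."""
    registry = registry if registry is not None else default_registry()
    names = [d.name for d in registry]
    rows = []
    for r in regions:
        for sp, seg in sorted(r.segments.items()):
            if set(seg.sequence) - set(STANDARD_AA) or not seg.sequence:
                continue
            vec = compute_feature_vector(seg.sequence, registry, scores=seg.scores)
            rows.append({"region_id": r.region_id, "species": sp, **dict(zip(names, vec.values))})
    return pd.DataFrame(rows)


def stage_traits(regions, tree, features_df, criticals):
    """BM and OU fits per (region, feature); LLR significance at the
    calibrated criticals.  Features with missing species values or zero
    variance in a region are recorded as missing tests."""
    feature_names = [c for c in features_df.columns if c not in ("region_id", "species")]
    rows = []
    for r in regions:
        sub = features_df[features_df.region_id == r.region_id].set_index("species")
        if len(sub) < 3:
            continue
        species = [sp for sp in tree.tip_labels if sp in set(sub.index)]
        pruned = prune_to_species(tree, species)
        X = sub.loc[pruned.tip_labels, feature_names].to_numpy(dtype=float)
        complete = ~np.isnan(X).any(axis=0)
        variable = np.nanstd(X, axis=0) > 0
        fit_cols = np.nonzero(complete & variable)[0]
        mu_bm = np.full(len(feature_names), np.nan)
        s2_bm = np.full(len(feature_names), np.nan)
        ll_bm = np.full(len(feature_names), np.nan)
        ou_fits = {}
        if fit_cols.size:
            m, s, ll = fit_bm_many(pruned, X[:, fit_cols])
            mu_bm[fit_cols], s2_bm[fit_cols], ll_bm[fit_cols] = m, s, ll
            for ci, fit in zip(fit_cols, fit_ou_many(pruned, X[:, fit_cols])):
                ou_fits[ci] = fit
        for j, name in enumerate(feature_names):
            fit = ou_fits.get(j)
            llr = float("nan")
            if fit is not None and np.isfinite(ll_bm[j]) and np.isfinite(fit.loglik):
                llr = fit.loglik - ll_bm[j]
            row = {
                "region_id": r.region_id,
                "feature": name,
                "mu_bm": mu_bm[j],
                "sigma2_bm": s2_bm[j],
                "mu_ou": fit.mu if fit else float("nan"),
                "sigma2_ou": fit.sigma2 if fit else float("nan"),
                "alpha": fit.alpha if fit else float("nan"),
                "loglik_bm": ll_bm[j],
                "loglik_ou": fit.loglik if fit else float("nan"),
                "llr": llr,
            }
            for level, crit in criticals.items():
                row[f"sig_{int(round(level * 100))}"] = bool(np.isfinite(llr) and llr > crit)
            rows.append(row)
    return pd.DataFrame(rows)


def llr_matrix_from_traits(trait_df, feature_names):
    """Pivot the trait-fit table into a regions x features LLR matrix."""
    pivot = trait_df.pivot(index="region_id", columns="feature", values="llr")
    pivot = pivot.reindex(columns=feature_names)
    return pivot


def run_pipeline(
    config: PipelineConfig,
    dataset_dir,
    out_dir,
    calibration_reps: int = 100,
    rate_grid=None,
    obo_path=None,
    gaf_path=None,
):
    """Run every stage on a dataset directory and write the artifact tables.

    Deterministic given ``config.rng_seed``; aborts with the stage name and
    alignment id on failure.  Returns the run log dict.
    """
    os.makedirs(out_dir, exist_ok=True)
    log: dict = {"config": {k: str(v) for k, v in vars(config).items()}}
    tree, alignments = load_dataset(dataset_dir)
    registry = default_registry()
    feature_names = [d.name for d in registry]

    stage = "call-regions"
    try:
        regions, region_log = stage_regions(alignments, tree, config)
        log[stage] = region_log
        region_df = pd.DataFrame(
            [
                {
                    "region_id": r.region_id,
                    "alignment_id": r.alignment_id,
                    "start": r.start,
                    "stop": r.stop,
                    "is_disorder": r.is_disorder,
                    "n_species": r.n_species,
                }
                for r in regions
            ]
        )
        region_df.to_csv(os.path.join(out_dir, "regions.tsv"), sep="\t", index=False)
        if not regions:
            raise ValueError("no regions survived filtering")

        stage = "fit-rates"
        rates_df, skipped = stage_rates(alignments, tree, regions, config)
        log[stage] = {"skipped_alignments": skipped, "n_regions": len(rates_df)}
        rates_df.to_csv(os.path.join(out_dir, "rates.tsv"), sep="\t", index=False, float_format="%.6g")

        stage = "features"
        features_df = stage_features(regions, registry)
        log[stage] = {"n_rows": len(features_df)}
        features_df.to_csv(os.path.join(out_dir, "features.tsv"), sep="\t", index=False, float_format="%.6g")

        stage = "calibrate"
        grid = list(rate_grid) if rate_grid is not None else DEFAULT_RATE_GRID
        criticals, per_rate, n_dropped = calibrate_critical_values(
            tree, grid, calibration_reps, config.alpha_levels, seed=config.stage_seed(stage)
        )
        log[stage] = {"criticals": {str(k): v for k, v in criticals.items()}, "n_dropped": n_dropped}
        with open(os.path.join(out_dir, "calibration.json"), "w") as fh:
            json.dump(
                {
                    "levels": list(config.alpha_levels),
                    "criticals": {str(k): v for k, v in criticals.items()},
                    "n_pooled": int(sum(len(v) for v in per_rate.values())),
                },
                fh,
                indent=1,
            )

        stage = "fit-traits"
        trait_df = stage_traits(regions, tree, features_df, criticals)
        log[stage] = {"n_tests": int(np.isfinite(trait_df.llr).sum()) if len(trait_df) else 0}
        trait_df.to_csv(os.path.join(out_dir, "trait_fits.tsv"), sep="\t", index=False, float_format="%.6g")

        stage = "cluster"
        llr_df = llr_matrix_from_traits(trait_df, feature_names) if len(trait_df) else pd.DataFrame()
        llr_df.to_csv(os.path.join(out_dir, "signatures.tsv"), sep="\t", float_format="%.6g")
        rates_idx = rates_df.set_index("region_id") if len(rates_df) else None
        cluster_rows = []
        if len(llr_df) >= 2 and rates_idx is not None:
            common = [rid for rid in llr_df.index if rid in rates_idx.index]
            aa = rates_idx.loc[common, "aa_rate"].to_numpy()
            ind = rates_idx.loc[common, "indel_rate"].to_numpy()
            fast_ids, _ = filter_by_rates(common, aa, ind, config.aa_rate_cutoff, config.indel_rate_cutoff)
            log[stage] = {"n_fast": len(fast_ids), "n_total": len(common)}
            target = fast_ids if len(fast_ids) >= 2 else common
            sigs = [Signature(rid, llr_df.loc[rid].to_numpy(dtype=float)) for rid in target]
            result = cluster_signatures(sigs)
            for rid, lab in zip(target, result.labels):
                cluster_rows.append({"region_id": rid, "cluster": int(lab)})
            per_region, per_feature = significance_counts(
                llr_df.loc[target].to_numpy(dtype=float), criticals
            )
            log[stage]["mean_significant_per_region"] = {
                str(lv): float(np.mean(v)) for lv, v in per_region.items()
            }
        pd.DataFrame(cluster_rows).to_csv(os.path.join(out_dir, "clusters.tsv"), sep="\t", index=False)

        stage = "enrich"
        if obo_path and gaf_path and cluster_rows:
            from .enrichment import hypergeom_enrichment, load_annotations

            ann = load_annotations(obo_path, gaf_path)
            region_to_gene = {row["region_id"]: row["region_id"].split(":")[0] for row in cluster_rows}
            ann.join_regions(region_to_gene)
            reference = [row["region_id"] for row in cluster_rows]
            enr_rows = []
            labels = sorted({row["cluster"] for row in cluster_rows})
            for lab in labels:
                members = [row["region_id"] for row in cluster_rows if row["cluster"] == lab]
                if not members:
                    continue
                for res in hypergeom_enrichment(members, reference, ann, cluster_id=str(lab)):
                    enr_rows.append(vars(res))
            pd.DataFrame(enr_rows).to_csv(
                os.path.join(out_dir, "enrichment.tsv"), sep="\t", index=False, float_format="%.6g"
            )
            log[stage] = {"n_tests": len(enr_rows)}
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(os.path.join(out_dir, "log.json"), "w") as fh:
        json.dump(log, fh, indent=1, default=str)
    return log
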