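"""Per-plate robust normalization (Z*-scores) and gene-level hit calling.

For each plate and cell-cycle class, a well's Z*-score is its relative
abundance minus the plate median, divided by the scaled median absolute
deviation:

    z*_{w,c} = (a_{w,c} - median_w' a_{w',c}) / (1.4826 * MAD_w' a_{w',c})

Median and MAD are taken over the plate's included *library* wells only;
control wells are scored against that distribution but never contribute to
it.  The default gene-level composite is the mean of the
proliferating-tetraploid class scores, z*(4CS) and z*(8CG2), which directly
encodes the screened phenotype (improved tetraploid proliferation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import ROLE_LIBRARY, ROLE_RLUC
from .profiles import PROLIFERATING_TETRAPLOID, SIX_CLASSES

MAD_SCALE = 1.4826  # consistency constant: scaled MAD estimates sigma under normality


def plate_zscores(
    profiles: pd.DataFrame,
    layout: pd.DataFrame,
    include_controls: bool = False,
    mad_scale: float = MAD_SCALE,
    min_wells: int = 8,
) -> pd.DataFrame:
    """Z*-scores per (plate, well, class), long format.

    ``profiles`` is the well-profile table from :func:`classify_wells`
    (columns a_<class>, qc_flag); ``layout`` the plate map.  QC-flagged
    wells are excluded from the plate statistics and receive no score.
    Classes with zero MAD on a plate yield NaN scores flagged ``mad_zero``
    (never +-inf).  Plates with fewer than ``min_wells`` included wells
    raise.
    """
    merged = profiles.merge(
        layout[["plate_id", "well", "role", "gene_id", "replicate"]], on=["plate_id", "well"], how="left"
    )
    rows = []
    for plate_id, grp in merged.groupby("plate_id", sort=False):
        in_stats = grp["qc_flag"].fillna("").eq("") & (
            grp["role"].isin([ROLE_LIBRARY]) if not include_controls else grp["role"].notna()
        )
        if int(in_stats.sum()) < min_wells:
            raise ValueError(
                f"plate {plate_id}: only {int(in_stats.sum())} included wells (< {min_wells})"
            )
        scored = grp[grp["qc_flag"].fillna("") == ""]
        for cls in SIX_CLASSES:
            a_ref = grp.loc[in_stats, f"a_{cls}"].to_numpy(dtype=float)
            med = float(np.median(a_ref))
            mad = float(np.median(np.abs(a_ref - med)))
            scale = mad_scale * mad
            a = scored[f"a_{cls}"].to_numpy(dtype=float)
            if scale == 0.0:
                z = np.full(len(a), np.nan)
                flag = "mad_zero"
            else:
                z = (a - med) / scale
                flag = ""
            rows.append(
                pd.DataFrame(
                    {
                        "plate_id": plate_id,
                        "well": scored["well"].to_numpy(),
                        "gene_id": scored["gene_id"].to_numpy(),
                        "role": scored["role"].to_numpy(),
                        "replicate": scored["replicate"].to_numpy(),
                        "cls": cls,
                        "z_star": z,
                        "flag": flag,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def _composite(ztab: pd.DataFrame, composite: str) -> pd.DataFrame:
    """Per-well composite score from a long Z*-score table."""
    wide = ztab.pivot(
        index=["plate_id", "well", "gene_id", "role", "replicate"],
        columns="cls",
        values="z_star",
    ).reset_index()
    pt = list(PROLIFERATING_TETRAPLOID)
    if composite == "mean_proliferating_tetraploid":
        wide["composite"] = wide[pt].mean(axis=1, skipna=False)
    elif composite == "max_proliferating_tetraploid":
        wide["composite"] = wide[pt].max(axis=1, skipna=False)
    elif composite in SIX_CLASSES:
        wide["composite"] = wide[composite]
    else:
        raise ValueError(f"unknown composite: {composite!r}")
    return wide


def gene_scores(
    zscores: pd.DataFrame,
    composite: str = "mean_proliferating_tetraploid",
) -> pd.DataFrame:
    """Per-gene per-replicate composites and the combined (mean) score.

    Only library wells enter gene scoring; a replicate whose composite is
    undefined (flagged class scores) is dropped from the combined mean, and
    a gene with no defined replicate keeps a NaN combined score, reported
    rather than silently zeroed.
    """
    wide = _composite(zscores, composite)
    lib = wide[wide["role"] == ROLE_LIBRARY]
    per_rep = lib.groupby(["gene_id", "replicate"], sort=False)["composite"].mean().reset_index()
    pivot = per_rep.pivot(index="gene_id", columns="replicate", values="composite")
    pivot.columns = [f"score_rep{int(r)}" for r in pivot.columns]
    pivot["combined"] = pivot.mean(axis=1, skipna=True)
    pivot["n_defined_replicates"] = pivot.filter(like="score_rep").notna().sum(axis=1)
    return pivot.reset_index()


def control_composites(
    zscores: pd.DataFrame, composite: str = "mean_proliferating_tetraploid"
) -> pd.DataFrame:
    """Per-well composite scores of the control wells (assay QC)."""
    wide = _composite(zscores, composite)
    return wide[wide["role"] != ROLE_LIBRARY][
        ["plate_id", "well", "gene_id", "role", "replicate", "composite"]
    ].reset_index(drop=True)


def negative_control_cut(
    zscores: pd.DataFrame,
    n_mads: float = 6.0,
    composite: str = "mean_proliferating_tetraploid",
) -> float:
    """Hit-calling cut derived from the R-LUC negative-control distribution.

    median + n_mads * (1.4826 * MAD) of the per-well neg-control composites.
    """
    ctrl = control_composites(zscores, composite)
    neg = ctrl.loc[ctrl["role"] == ROLE_RLUC, "composite"].dropna().to_numpy()
    if len(neg) == 0:
        raise ValueError("no negative-control composites available")
    med = float(np.median(neg))
    mad = float(np.median(np.abs(neg - med)))
    return med + n_mads * MAD_SCALE * mad


def call_hits(
    scores: pd.DataFrame,
    primary_threshold: float = 3.0,
    replicate_rule: str = "union",
    high_conf_cut: float = 10.0,
) -> pd.DataFrame:
    """Primary and high-confidence hit calls from gene scores.

    Primary: composite above ``primary_threshold`` in at least one replicate
    (union rule, the false-negative-sparing default), in every replicate
    (intersection), or combined above threshold (mean).  High-confidence:
    combined score above ``high_conf_cut``.
    """
    if primary_threshold <= 0 or high_conf_cut <= 0:
        raise ValueError("thresholds must be positive")
    out = scores.copy()
    rep_cols = [c for c in out.columns if c.startswith("score_rep")]
    above = out[rep_cols] > primary_threshold
    if replicate_rule == "union":
        out["is_primary"] = above.any(axis=1)
    elif replicate_rule == "intersection":
        out["is_primary"] = above.all(axis=1) & out[rep_cols].notna().all(axis=1)
    elif replicate_rule == "mean":
        out["is_primary"] = out["combined"] > primary_threshold
    else:
        raise ValueError(f"unknown replicate_rule: {replicate_rule!r}")
    out["is_high_confidence"] = out["combined"] > high_conf_cut
    return out


def high_confidence_genes(summary: pd.DataFrame, z_cut: float = 10.0, score_col: str = "combined") -> pd.DataFrame:
    """Filter a screen-summary table to genes scoring above ``z_cut``."""
    return summary[summary[score_col] > z_cut].reset_index(drop=True)
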