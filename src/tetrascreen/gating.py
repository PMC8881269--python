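"""Six-class ploidy/cell-cycle classification from DNA content and FUCCI state.

A cell's relative DNA content ``c = dapi_int / anchor`` (anchor = intensity
of the diploid-G1 peak) and its FUCCI sensor state together determine the
class:

===========  ==============================  =========
FUCCI state  content window                  class
===========  ==============================  =========
G1 only      [0.75, 1.25]                    2CG1
G1 only      [1.75, 2.25]                    4CG1
G2 / both    [0.75, 1.75)                    2CS
G2 only      [1.75, 2.25]                    4CG2
both         [1.75, 2.25]                    4CS (tetraploid early S)
G2 / both    (2.25, 3.5)                     4CS
G2 / both    [3.5, 4.5]                      8CG2
none         —                               excluded
otherwise    —                               other
===========  ==============================  =========

Cells with no FUCCI signal are excluded; cells whose content falls outside
any window for their state are "other" — both are kept out of the class
abundances but counted for QC.  All boundaries live in :class:`GatingConfig`
and are overridable (the windows are design choices in relative-content
units, not biological constants).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import gaussian_kde
from skimage.filters import threshold_otsu

from .profiles import SIX_CLASSES

EXCLUDED = "excluded"
OTHER = "other"

STATE_G1 = "G1only"
STATE_G2 = "G2only"
STATE_BOTH = "both"
STATE_NONE = "none"


@dataclass
class GatingConfig:
    """Thresholds and content windows for classification.

    FUCCI thresholds may be absolute intensities or ``None`` to be resolved
    per plate from the bimodal log-intensity distribution (Otsu valley).
    """

    g1_threshold: float | None = None
    g2_threshold: float | None = None
    g1_window_2c: tuple[float, float] = (0.75, 1.25)
    g1_window_4c: tuple[float, float] = (1.75, 2.25)
    s_diploid: tuple[float, float] = (1.25, 1.75)
    s_tetraploid: tuple[float, float] = (2.25, 3.5)
    g2_tetraploid: tuple[float, float] = (3.5, 4.5)
    min_cells: int = 100  # below this, a well is QC-flagged
    anchor_min_fucci: int = 50  # minimum FUCCI-positive cells for a well anchor

    def __post_init__(self) -> None:
        windows = [self.g1_window_2c, self.s_diploid, self.g1_window_4c, self.s_tetraploid, self.g2_tetraploid]
        flat = [b for w in windows for b in w]
        if any(b <= 0 for b in flat) or flat != sorted(flat):
            raise ValueError("content windows must be positive, disjoint and ordered")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "GatingConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)


def _log_valley_threshold(values: np.ndarray) -> float:
    """Threshold separating the on/off modes of a positive intensity set."""
    v = np.asarray(values, dtype=float)
    v = v[v > 0]
    logv = np.log(v)
    if logv.max() - logv.min() < 1e-9:
        return float(np.exp(logv.mean()))
    return float(np.exp(threshold_otsu(logv)))


def resolve_fucci_thresholds(
    records: pd.DataFrame, config: GatingConfig | None = None
) -> tuple[float, float]:
    """Absolute FUCCI on/off thresholds for a set of records (one plate)."""
    cfg = config or GatingConfig()
    g1_thr = cfg.g1_threshold if cfg.g1_threshold is not None else _log_valley_threshold(records["g1_int"])
    g2_thr = cfg.g2_threshold if cfg.g2_threshold is not None else _log_valley_threshold(records["g2_int"])
    return float(g1_thr), float(g2_thr)


def fucci_state(
    g1_int: np.ndarray | float, g2_int: np.ndarray | float, g1_threshold: float, g2_threshold: float
) -> np.ndarray:
    """Vectorized FUCCI state from threshold exceedance of the two sensors."""
    g1 = np.atleast_1d(np.asarray(g1_int, dtype=float)) > g1_threshold
    g2 = np.atleast_1d(np.asarray(g2_int, dtype=float)) > g2_threshold
    return np.select(
        [g1 & ~g2, ~g1 & g2, g1 & g2],
        [STATE_G1, STATE_G2, STATE_BOTH],
        default=STATE_NONE,
    ).astype(object)


def estimate_2c_anchor(
    records: pd.DataFrame,
    config: GatingConfig | None = None,
    thresholds: tuple[float, float] | None = None,
) -> float:
    """Intensity of the diploid-G1 DAPI peak.

    The anchor is located on the kernel-smoothed histogram of log DAPI among
    G1-sensor-only cells as the *lowest-content substantial mode* (peak
    height at least 20% of the tallest peak).  In a tetraploid-heavy
    population the tallest G1 peak is the 4C one, so taking the leftmost
    substantial peak — rather than the global mode — is what identifies the
    2C G1 peak.  Deterministic.  Raises when fewer than
    ``anchor_min_fucci`` FUCCI-positive cells are available; callers should
    then pool records at the plate level.
    """
    cfg = config or GatingConfig()
    g1_thr, g2_thr = thresholds or resolve_fucci_thresholds(records, cfg)
    states = fucci_state(records["g1_int"].to_numpy(), records["g2_int"].to_numpy(), g1_thr, g2_thr)
    n_fucci = int((states != STATE_NONE).sum())
    if n_fucci < cfg.anchor_min_fucci:
        raise ValueError(
            f"only {n_fucci} FUCCI-positive cells (< {cfg.anchor_min_fucci}); "
            "pool records at the plate level to estimate the anchor"
        )
    dapi = records["dapi_int"].to_numpy(dtype=float)
    sel = dapi[(states == STATE_G1) & (dapi > 0)]
    if len(sel) == 0:
        raise ValueError("no G1-sensor-only cells; cannot locate the 2C G1 peak")
    logs = np.log(sel)
    if logs.max() - logs.min() < 1e-9 or len(logs) < 3:
        return float(np.exp(logs.mean()))
    kde = gaussian_kde(logs)
    bw = float(kde.factor) * float(logs.std(ddof=1))
    grid = np.linspace(logs.min() - 3 * bw, logs.max() + 3 * bw, 512)
    dens = kde(grid)
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] > dens[2:])
    peaks = np.flatnonzero(interior) + 1
    peaks = peaks[dens[peaks] >= 0.2 * dens.max()]
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(dens))])
    return float(np.exp(grid[peaks[0]]))


def _in(c: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    return (c >= window[0]) & (c <= window[1])


def classify_cells(
    records: pd.DataFrame,
    anchor: float,
    config: GatingConfig | None = None,
    thresholds: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Assign each record a class; adds content, fucci_state and cls columns.

    ``anchor`` must be positive; non-finite intensities raise.
    """
    cfg = config or GatingConfig()
    if not anchor > 0:
        raise ValueError("anchor must be > 0")
    for col in ("dapi_int", "g1_int", "g2_int"):
        if not np.isfinite(records[col].to_numpy(dtype=float)).all():
            raise ValueError(f"non-finite intensities in {col}")
    g1_thr, g2_thr = thresholds or resolve_fucci_thresholds(records, cfg)
    states = fucci_state(records["g1_int"].to_numpy(), records["g2_int"].to_numpy(), g1_thr, g2_thr)
    c = records["dapi_int"].to_numpy(dtype=float) / anchor

    is_g1 = states == STATE_G1
    is_g2 = states == STATE_G2
    is_both = states == STATE_BOTH
    g2ish = is_g2 | is_both

    cls = np.full(len(records), OTHER, dtype=object)
    cls[states == STATE_NONE] = EXCLUDED
    cls[is_g1 & _in(c, cfg.g1_window_2c)] = "2CG1"
    cls[is_g1 & _in(c, cfg.g1_window_4c)] = "4CG1"
    # diploid S spans the 2C window plus the inter-anchor region
    cls[g2ish & (c >= cfg.g1_window_2c[0]) & (c < cfg.g1_window_4c[0])] = "2CS"
    in_4c = _in(c, cfg.g1_window_4c)
    cls[is_g2 & in_4c] = "4CG2"
    cls[is_both & in_4c] = "4CS"  # both sensors at 4C: tetraploid early S
    cls[g2ish & (c > cfg.s_tetraploid[0]) & (c < cfg.s_tetraploid[1])] = "4CS"
    cls[g2ish & _in(c, cfg.g2_tetraploid)] = "8CG2"

    out = records.copy()
    out["content"] = c
    out["fucci_state"] = states
    out["cls"] = cls
    return out


@dataclass
class WellProfile:
    """Class counts and relative abundances for one well."""

    plate_id: str
    well: str
    counts: dict[str, int]
    n_excluded: int
    n_other: int
    qc_flags: list[str] = field(default_factory=list)

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values())

    @property
    def abundances(self) -> dict[str, float]:
        total = self.n_classified
        if total == 0:
            return {c: float("nan") for c in SIX_CLASSES}
        return {c: self.counts[c] / total for c in SIX_CLASSES}


def summarize_well(
    classified: pd.DataFrame,
    plate_id: str = "",
    well: str = "",
    config: GatingConfig | None = None,
) -> WellProfile:
    """Reduce classified records of one well to counts and abundances.

    A well with zero classified cells keeps NaN abundances and is flagged
    ``empty`` (never silently zero-filled); below ``min_cells`` classified
    cells it is flagged ``low_cells``.
    """
    cfg = config or GatingConfig()
    vc = classified["cls"].value_counts()
    counts = {c: int(vc.get(c, 0)) for c in SIX_CLASSES}
    prof = WellProfile(
        plate_id=plate_id or (classified["plate_id"].iloc[0] if "plate_id" in classified and len(classified) else ""),
        well=well or (classified["well"].iloc[0] if "well" in classified and len(classified) else ""),
        counts=counts,
        n_excluded=int(vc.get(EXCLUDED, 0)),
        n_other=int(vc.get(OTHER, 0)),
    )
    if prof.n_classified == 0:
        prof.qc_flags.append("empty")
    elif prof.n_classified < cfg.min_cells:
        prof.qc_flags.append("low_cells")
    return prof


def _profiles_frame(profiles: list[WellProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        ab = p.abundances
        rows.append(
            {
                "plate_id": p.plate_id,
                "well": p.well,
                **{f"n_{c}": p.counts[c] for c in SIX_CLASSES},
                **{f"a_{c}": ab[c] for c in SIX_CLASSES},
                "n_other": p.n_other,
                "n_excluded": p.n_excluded,
                "qc_flag": ";".join(p.qc_flags),
            }
        )
    return pd.DataFrame(rows)


def classify_wells(
    cells: pd.DataFrame, config: GatingConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify a multi-well cell table and summarize per well.

    FUCCI thresholds are resolved per plate; the 2C anchor is estimated per
    well, falling back to the pooled plate anchor when a well has too few
    FUCCI-positive cells.  Returns (classified cells, well-profile table).
    """
    cfg = config or GatingConfig()
    classified_chunks = []
    profiles: list[WellProfile] = []
    for plate_id, plate_cells in cells.groupby("plate_id", sort=False):
        thresholds = resolve_fucci_thresholds(plate_cells, cfg)
        try:
            plate_anchor = estimate_2c_anchor(plate_cells, cfg, thresholds)
        except ValueError:
            plate_anchor = None
        for well, wcells in plate_cells.groupby("well", sort=False):
            try:
                anchor = estimate_2c_anchor(wcells, cfg, thresholds)
                # A knockdown that depletes diploid G1 can leave too few 2C
                # cells for a stable well-level peak; staining varies by tens
                # of percent, not 2-fold, so a well anchor far from the plate
                # anchor marks a failed estimate, not real variation.
                if plate_anchor is not None and not (1 / 1.5 < anchor / plate_anchor < 1.5):
                    anchor = plate_anchor
            except ValueError:
                anchor = plate_anchor
            if anchor is None:
                prof = WellProfile(plate_id, well, {c: 0 for c in SIX_CLASSES}, 0, 0, ["no_anchor"])
                profiles.append(prof)
                continue
            cl = classify_cells(wcells, anchor, cfg, thresholds)
            classified_chunks.append(cl)
            profiles.append(summarize_well(cl, plate_id, well, cfg))
    classified = (
        pd.concat(classified_chunks, ignore_index=True) if classified_chunks else pd.DataFrame()
    )
    return classified, _profiles_frame(profiles)
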