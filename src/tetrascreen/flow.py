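"""Flow-cytometry gating of DNA/EdU/cyclin-B event tables.

Events from the FACS-based proliferation assay are gated into five reported
categories — 2C_G1 (diploid G1), 2C_S (diploid S/G2/M), 4C_G1 (tetraploid
G1), 4C_S (tetraploid S) and 8C_G2 (tetraploid G2/M) — plus "other".  EdU
incorporation marks replicating cells; the cyclin-B stain resolves the 4C
EdU-negative ambiguity between diploid G2/M (cyclin-B high, pooled into
2C_S) and tetraploid G1 (cyclin-B low).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from skimage.filters import threshold_otsu

FLOW_CLASSES = ("2C_G1", "2C_S", "4C_G1", "4C_S", "8C_G2", "other")


def _log_otsu(values: np.ndarray) -> float:
    v = np.asarray(values, dtype=float)
    v = v[v > 0]
    logv = np.log(v)
    if logv.max() - logv.min() < 1e-9:
        return float(np.exp(logv.mean()))
    return float(np.exp(threshold_otsu(logv)))


def estimate_dapi_anchor(dapi: np.ndarray) -> float:
    """DNA-content anchor (2C peak) from the DAPI histogram.

    Lowest substantial mode (>= 20% of the tallest peak) of the
    kernel-smoothed log-DAPI density.
    """
    v = np.asarray(dapi, dtype=float)
    v = v[v > 0]
    if len(v) < 10:
        raise ValueError("too few events to estimate the 2C anchor")
    logs = np.log(v)
    if logs.max() - logs.min() < 1e-9:
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


def gate_flow_events(
    events: pd.DataFrame,
    anchor: float | None = None,
    edu_threshold: float | None = None,
    cycb_threshold: float | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify flow events and return (classified events, class fractions).

    Rules on relative content ``c = dapi / anchor``:

    - EdU+  and c in (0.75, 2.25]  -> 2C_S   (diploid S)
    - EdU+  and c in (2.25, 4.5)   -> 4C_S   (tetraploid S)
    - EdU-  and c in (0.75, 1.25]  -> 2C_G1
    - EdU-  and c in (1.75, 2.25]  -> 4C_G1 if cyclin-B low, else 2C_S
      (cyclin-B high marks diploid G2/M, reported within 2C_S)
    - EdU-  and c in (3.5, 4.5]    -> 8C_G2
    - otherwise                    -> other

    Without a cyclin-B column the 4C EdU- events cannot be resolved; they
    are labelled "other" and a warning is emitted.  Fractions cover all six
    labels and sum to 1.
    """
    dapi = events["dapi"].to_numpy(dtype=float)
    edu = events["edu"].to_numpy(dtype=float)
    if anchor is None:
        anchor = estimate_dapi_anchor(dapi)
    if edu_threshold is None:
        edu_threshold = _log_otsu(edu)
    c = dapi / anchor
    edu_pos = edu > edu_threshold

    has_cycb = "cycb" in events.columns
    if has_cycb:
        cycb = events["cycb"].to_numpy(dtype=float)
        if cycb_threshold is None:
            cycb_threshold = _log_otsu(cycb)
        cycb_high = cycb > cycb_threshold

    cls = np.full(len(events), "other", dtype=object)
    cls[edu_pos & (c > 0.75) & (c <= 2.25)] = "2C_S"
    cls[edu_pos & (c > 2.25) & (c < 4.5)] = "4C_S"
    cls[~edu_pos & (c > 0.75) & (c <= 1.25)] = "2C_G1"
    amb = ~edu_pos & (c > 1.75) & (c <= 2.25)
    if has_cycb:
        cls[amb & ~cycb_high] = "4C_G1"
        cls[amb & cycb_high] = "2C_S"
    elif amb.any():
        warnings.warn(
            f"{int(amb.sum())} 4C EdU-negative events are ambiguous without a "
            "cyclin-B column; labelled 'other'",
            stacklevel=2,
        )
    cls[~edu_pos & (c > 3.5) & (c <= 4.5)] = "8C_G2"

    out = events.copy()
    out["content"] = c
    out["edu_positive"] = edu_pos
    out["cls"] = cls
    fractions = pd.Series(
        {name: float((cls == name).mean()) if len(cls) else np.nan for name in FLOW_CLASSES},
        name="fraction",
    )
    return out, fractions


def proliferation_fold_change(
    treated_fractions: pd.Series | dict,
    control_fractions: pd.Series | dict,
    definition: str = "proliferating_tetraploid",
) -> float:
    """Fold change of the proliferating-tetraploid fraction, treated/control.

    Default definition: (4C_S + 8C_G2) / (4C_G1 + 4C_S + 8C_G2) within each
    sample, then the ratio of the two.  ``definition="edu_tetraploid"``
    restricts the numerator to EdU-positive tetraploids (4C_S alone).
    Requires a positive control fraction.
    """

    def frac(fr) -> float:
        fr = dict(fr)
        tet = fr["4C_G1"] + fr["4C_S"] + fr["8C_G2"]
        if tet == 0:
            raise ValueError("no tetraploid events; fraction undefined")
        if definition == "proliferating_tetraploid":
            return (fr["4C_S"] + fr["8C_G2"]) / tet
        if definition == "edu_tetraploid":
            return fr["4C_S"] / tet
        raise ValueError(f"unknown definition: {definition!r}")

    control = frac(control_fractions)
    if control == 0:
        raise ValueError("control proliferating fraction is zero; fold change undefined")
    return frac(treated_fractions) / control
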