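"""Synthetic screen generator with known ground truth.

Every well draws cells from a realized class profile: the baseline
DCD-treated mixture, optionally shifted by a planted knockdown effect
(log-odds on the proliferating-tetraploid classes) and perturbed by
per-plate lognormal class factors.  Intensities follow a simple generative
model: integrated DAPI is lognormal around the class DNA content (2C -> 1x
anchor, 4C -> 2x, 8C -> 4x; S-phase classes uniform between the flanking
contents), FUCCI sensors are lognormal around an "on" or "off" mean with a
configurable early-S both-sensors-on fraction, and binucleated tetraploids
are emitted as a single record with ``n_nuclei = 2`` and per-nucleus DAPI
draws summed.

Reproducibility: one master seed; each well derives an independent RNG
stream by stable hashing of (plate, well), so results do not depend on the
order wells are simulated in.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import ScreenDesign
from .profiles import STATE_NAMES, ClassProfile, apply_knockdown_effect, dcd_default_profile

CELL_TABLE_COLUMNS = [
    "plate_id",
    "well",
    "cell_id",
    "dapi_int",
    "g1_int",
    "g2_int",
    "n_nuclei",
    "true_class",
]

#: Relative DNA content anchors per state (S classes drawn uniform in a range).
_CONTENT = {"2CG1": 1.0, "4CG2": 2.0, "4CG1": 2.0, "8CG2": 4.0}
_BINUCLEATE = {"4CG1", "4CS", "8CG2"}
_G1_ON = {"2CG1", "4CG1"}
_S_CLASSES = {"2CS", "4CS"}


@dataclass(frozen=True)
class IntensityModel:
    """Generative intensity model for one well.

    anchor_2c
        Integrated DAPI intensity of a mononucleated 2C (diploid G1) cell,
        arbitrary units.
    dapi_cv
        Lognormal coefficient of variation of integrated DAPI per nucleus.
    fucci_on_mean / fucci_off_mean
        Median integrated intensity of an expressed / silent FUCCI sensor
        (20x separation by default keeps the on/off gates learnable).
    fucci_cv
        Lognormal CV of the FUCCI intensities.
    early_s_both_fraction
        Fraction of S-phase cells still carrying the G1 sensor (Cdt1
        reporter persisting into early S) and therefore positive for both.
    well_factor
        Multiplicative factor applied to all three channels of the well
        (staining/illumination variation).
    s_content_ranges
        Relative-content ranges the S classes draw from, uniform.  The
        default spans the full gap between the flanking contents; tests of
        gate-core behaviour may narrow these.
    """

    anchor_2c: float = 1000.0
    dapi_cv: float = 0.12
    fucci_on_mean: float = 500.0
    fucci_off_mean: float = 25.0
    fucci_cv: float = 0.25
    early_s_both_fraction: float = 0.25
    well_factor: float = 1.0
    s_content_ranges: dict = field(
        default_factory=lambda: {"2CS": (1.0, 2.0), "4CS": (2.0, 4.0)}
    )

    def with_noise_off(self) -> "IntensityModel":
        return replace(self, dapi_cv=0.0, fucci_cv=0.0)


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _median_lognormal(rng: np.random.Generator, median: np.ndarray, sigma: float) -> np.ndarray:
    """Lognormal draws with the given median (exact values when sigma == 0)."""
    if sigma == 0.0:
        return np.asarray(median, dtype=float).copy()
    return np.asarray(median) * np.exp(rng.normal(0.0, sigma, size=np.shape(median)))


def well_rng(master_seed: int, plate_id: str, well: str) -> np.random.Generator:
    """Independent, order-insensitive RNG stream for one well."""
    digest = hashlib.sha256(f"{plate_id}:{well}".encode()).digest()
    stream = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, stream]))


def _simulate_well_arrays(
    profile: ClassProfile, n_cells: int, model: IntensityModel, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    classes = rng.choice(len(STATE_NAMES), size=n_cells, p=profile.probs)
    names = np.array(STATE_NAMES, dtype=object)[classes]

    content = np.empty(n_cells)
    for cls, c in _CONTENT.items():
        content[names == cls] = c
    for cls, (lo, hi) in model.s_content_ranges.items():
        m = names == cls
        content[m] = rng.uniform(lo, hi, size=int(m.sum()))
    # FUCCI-negative cells are a mix of unreported diploid and tetraploid cells.
    m = names == "FUCCI_neg"
    content[m] = rng.choice([1.0, 2.0], size=int(m.sum()))

    n_nuclei = np.where(np.isin(names, list(_BINUCLEATE)), 2, 1).astype(np.int64)

    sigma_dapi = _lognormal_sigma(model.dapi_cv)
    target = content * model.anchor_2c * model.well_factor
    dapi = np.where(
        n_nuclei == 2,
        _median_lognormal(rng, target / 2, sigma_dapi) + _median_lognormal(rng, target / 2, sigma_dapi),
        _median_lognormal(rng, target, sigma_dapi),
    )

    g1_on = np.isin(names, list(_G1_ON))
    g2_on = np.isin(names, list(_S_CLASSES | {"4CG2", "8CG2"}))
    early_s = np.isin(names, list(_S_CLASSES)) & (
        rng.uniform(size=n_cells) < model.early_s_both_fraction
    )
    g1_on = g1_on | early_s

    sigma_f = _lognormal_sigma(model.fucci_cv)
    scale = model.well_factor
    g1_med = np.where(g1_on, model.fucci_on_mean, model.fucci_off_mean) * scale
    g2_med = np.where(g2_on, model.fucci_on_mean, model.fucci_off_mean) * scale
    g1 = _median_lognormal(rng, g1_med, sigma_f)
    g2 = _median_lognormal(rng, g2_med, sigma_f)

    return {
        "cell_id": np.arange(1, n_cells + 1),
        "dapi_int": dapi,
        "g1_int": g1,
        "g2_int": g2,
        "n_nuclei": n_nuclei,
        "true_class": names,
    }


def simulate_well(
    profile: ClassProfile,
    n_cells: int,
    intensity_model: IntensityModel | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw one well's cell records from a class profile.

    Returns a table with cell_id, dapi_int, g1_int, g2_int, n_nuclei and
    true_class; a fixed seed yields identical output.
    """
    model = intensity_model or IntensityModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return pd.DataFrame(_simulate_well_arrays(profile, n_cells, model, rng))


@dataclass
class TruthConfig:
    """Planted-effect configuration for a synthetic screen."""

    hit_fraction: float = 0.02
    effect_size: float = 1.5  # log-odds shift of {4CS, 8CG2}
    plate_effect_sd: float = 0.05  # lognormal SD of per-(plate, class) factors
    n_cells_per_well: int = 500
    base_profile: ClassProfile = field(default_factory=dcd_default_profile)
    intensity_model: IntensityModel = field(default_factory=IntensityModel)

    def __post_init__(self) -> None:
        if not 0.0 <= self.hit_fraction <= 1.0:
            raise ValueError("hit_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted truth for a simulated screen.

    genes:   gene_id, is_tp53_like, effect_size (0 for nulls and R-LUC).
    wells:   per-well realized profile (p_<state> columns) with layout info.
    plate_factors: per-plate multiplicative class factors.
    """

    genes: pd.DataFrame
    wells: pd.DataFrame
    plate_factors: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)


def simulate_screen(
    design: ScreenDesign,
    truth_config: TruthConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate every well of a designed screen.

    Positive-control wells (TP53, KIFC1) carry the reference planted effect;
    R-LUC and empty wells carry zero effect; ``round(hit_fraction *
    n_genes)`` library genes are drawn (quota sampling, seeded) as TP53-like
    hits with the configured effect size.  Returns the concatenated cell
    table and the full ground truth.  Output is reproducible by seed and
    independent of well iteration order.
    """
    cfg = truth_config or TruthConfig()
    genes = design.library_genes
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xA5A5]))
    n_hits = int(round(cfg.hit_fraction * len(genes)))
    hit_genes = set(rng.choice(genes, size=n_hits, replace=False)) if n_hits else set()

    effect_by_gene = {g: (cfg.effect_size if g in hit_genes else 0.0) for g in genes}
    effect_by_gene["TP53"] = cfg.effect_size
    effect_by_gene["KIFC1"] = cfg.effect_size
    effect_by_gene["RLUC"] = 0.0
    effect_by_gene[""] = 0.0

    gene_rows = [(g, g in hit_genes, effect_by_gene[g]) for g in genes]
    gene_rows += [("TP53", True, cfg.effect_size), ("KIFC1", True, cfg.effect_size), ("RLUC", False, 0.0)]
    truth_genes = pd.DataFrame(gene_rows, columns=["gene_id", "is_tp53_like", "effect_size"])

    # Per-(plate, class) lognormal factors; a scalar factor common to all
    # classes would cancel under renormalization, so each class gets its own.
    plates = design.plates
    factor_rows = {}
    for plate_id in plates:
        prng = well_rng(seed, plate_id, "__plate__")
        factor_rows[plate_id] = (
            prng.lognormal(0.0, cfg.plate_effect_sd, size=len(STATE_NAMES))
            if cfg.plate_effect_sd > 0
            else np.ones(len(STATE_NAMES))
        )
    plate_factors = pd.DataFrame.from_dict(factor_rows, orient="index", columns=list(STATE_NAMES))
    plate_factors.index.name = "plate_id"

    shifted_cache: dict[float, ClassProfile] = {}

    def shifted(effect: float) -> ClassProfile:
        if effect not in shifted_cache:
            shifted_cache[effect] = apply_knockdown_effect(cfg.base_profile, effect)
        return shifted_cache[effect]

    chunks = []
    well_rows = []
    layout = design.table
    for plate_id, well, role, gene_id in zip(
        layout["plate_id"], layout["well"], layout["role"], layout["gene_id"]
    ):
        factors = factor_rows[plate_id]
        base = shifted(effect_by_gene.get(gene_id, 0.0))
        w = base.probs * factors
        realized = ClassProfile(w / w.sum())
        rng_w = well_rng(seed, plate_id, well)
        n_cells = 0 if role == "empty" else cfg.n_cells_per_well
        arrays = _simulate_well_arrays(realized, n_cells, cfg.intensity_model, rng_w)
        n = len(arrays["cell_id"])
        chunk = pd.DataFrame(arrays)
        chunk.insert(0, "plate_id", plate_id)
        chunk.insert(1, "well", well)
        chunks.append(chunk)
        well_rows.append((plate_id, well, gene_id, role, *realized.probs))

    cells = pd.concat(chunks, ignore_index=True)[CELL_TABLE_COLUMNS]
    wells = pd.DataFrame(
        well_rows,
        columns=["plate_id", "well", "gene_id", "role"] + [f"p_{s}" for s in STATE_NAMES],
    )
    return cells, GroundTruth(genes=truth_genes, wells=wells, plate_factors=plate_factors)


# ---------------------------------------------------------------------------
# Flow-cytometry-like event tables (for the downstream validation assay)

#: Generation states for flow events: (content spec, edu_on, cycb_on, label).
_FLOW_STATES = {
    "2C_G1": (1.0, False, False, "2C_G1"),
    "2C_Sphase": ((1.0, 2.0), True, False, "2C_S"),
    "2C_G2M": (2.0, False, True, "2C_S"),  # diploid G2/M reports as 2C_S
    "4C_G1": (2.0, False, False, "4C_G1"),
    "4C_Sphase": ((2.0, 4.0), True, False, "4C_S"),
    "8C_G2M": (4.0, False, True, "8C_G2"),
}

DEFAULT_FLOW_FRACTIONS = {
    "2C_G1": 0.15,
    "2C_Sphase": 0.10,
    "2C_G2M": 0.05,
    "4C_G1": 0.35,
    "4C_Sphase": 0.22,
    "8C_G2M": 0.13,
}


def simulate_flow_events(
    fractions: dict[str, float] | None = None,
    n_events: int = 10_000,
    anchor: float = 50_000.0,
    dapi_cv: float = 0.08,
    marker_on: float = 5_000.0,
    marker_off: float = 150.0,
    marker_cv: float = 0.35,
    seed: int = 0,
) -> pd.DataFrame:
    """DNA/EdU/cyclin-B event table emulating the FACS proliferation assay.

    ``fractions`` gives the mix over the six generation states (diploid
    G1/S/G2M, tetraploid G1/S/G2M); the returned ``true_class`` column uses
    the five reported categories (diploid S, G2 and M are pooled as 2C_S).
    """
    fr = dict(DEFAULT_FLOW_FRACTIONS if fractions is None else fractions)
    states = list(fr)
    p = np.array([fr[s] for s in states], dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(states), size=n_events, p=p)
    names = np.array(states, dtype=object)[draws]

    content = np.empty(n_events)
    edu_on = np.zeros(n_events, dtype=bool)
    cycb_on = np.zeros(n_events, dtype=bool)
    label = np.empty(n_events, dtype=object)
    for s, (cspec, e_on, c_on, lab) in _FLOW_STATES.items():
        m = names == s
        if not m.any():
            continue
        if isinstance(cspec, tuple):
            content[m] = rng.uniform(cspec[0], cspec[1], size=int(m.sum()))
        else:
            content[m] = cspec
        edu_on[m] = e_on
        cycb_on[m] = c_on
        label[m] = lab

    sig_d = _lognormal_sigma(dapi_cv)
    sig_m = _lognormal_sigma(marker_cv)
    dapi = _median_lognormal(rng, content * anchor, sig_d)
    edu = _median_lognormal(rng, np.where(edu_on, marker_on, marker_off), sig_m)
    cycb = _median_lognormal(rng, np.where(cycb_on, marker_on, marker_off), sig_m)
    return pd.DataFrame(
        {"dapi": dapi, "edu": edu, "cycb": cycb, "true_class": label}
    )
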