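"""Screen plate layouts: gene-to-well assignment with control wells.

A screen design maps every library gene to ``n_replicates`` wells (one per
plate copy, same well position on each copy) and reserves fixed positions on
every plate for control wells: non-targeting R-LUC negative controls plus
TP53 and KIFC1 positive controls, whose knockdown is expected to boost
tetraploid proliferation.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

ROLE_LIBRARY = "library"
ROLE_RLUC = "neg_ctrl_RLUC"
ROLE_TP53 = "pos_ctrl_TP53"
ROLE_KIFC1 = "pos_ctrl_KIFC1"
ROLE_EMPTY = "empty"

CONTROL_ROLES = (ROLE_RLUC, ROLE_TP53, ROLE_KIFC1)

_CONTROL_GENE = {ROLE_RLUC: "RLUC", ROLE_TP53: "TP53", ROLE_KIFC1: "KIFC1"}

_PLATE_DIMS = {96: (8, 12), 384: (16, 24)}

#: Default number of control wells per plate, by role.
DEFAULT_CONTROLS = {ROLE_RLUC: 16, ROLE_TP53: 4, ROLE_KIFC1: 4}

PLATE_MAP_COLUMNS = ["plate_id", "well", "role", "gene_id", "replicate"]


class DesignError(ValueError):
    """Raised when a requested layout cannot fit on the plate format."""


def well_names(plate_format: int) -> list[str]:
    """Row-major well identifiers for a plate format (e.g. A1..P24 for 384)."""
    try:
        n_rows, n_cols = _PLATE_DIMS[plate_format]
    except KeyError:
        raise DesignError(f"unsupported plate format: {plate_format!r}") from None
    rows = string.ascii_uppercase[:n_rows]
    return [f"{r}{c}" for r in rows for c in range(1, n_cols + 1)]


@dataclass
class ScreenDesign:
    """A plate map: one row per well per plate copy.

    ``table`` has columns plate_id, well, role, gene_id, replicate.
    """

    table: pd.DataFrame
    plate_format: int
    n_replicates: int
    seed: int

    @property
    def plates(self) -> list[str]:
        return list(pd.unique(self.table["plate_id"]))

    @property
    def library_genes(self) -> list[str]:
        lib = self.table.loc[self.table["role"] == ROLE_LIBRARY, "gene_id"]
        return list(pd.unique(lib))

    def validate(self) -> None:
        t = self.table
        if list(t.columns) != PLATE_MAP_COLUMNS:
            raise DesignError(f"plate map must have columns {PLATE_MAP_COLUMNS}")
        if t.duplicated(["plate_id", "well"]).any():
            raise DesignError("well ids must be unique within a plate")
        counts = t[t["role"] == ROLE_LIBRARY].groupby("gene_id").size()
        if not (counts == self.n_replicates).all():
            bad = counts[counts != self.n_replicates]
            raise DesignError(f"library genes without {self.n_replicates} wells: {bad.index.tolist()[:5]}")
        per_plate = t.groupby("plate_id")["role"].value_counts().unstack(fill_value=0)
        if (per_plate.get(ROLE_RLUC, 0) < 4).any():
            raise DesignError("every plate needs >=4 R-LUC negative-control wells")
        for role in (ROLE_TP53, ROLE_KIFC1):
            if (per_plate.get(role, 0) < 2).any():
                raise DesignError(f"every plate needs >=2 {role} wells")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, plate_format: int = 384) -> "ScreenDesign":
        t = pd.read_csv(path, dtype={"well": str, "plate_id": str, "gene_id": str}, keep_default_na=False)
        n_rep = int(t.loc[t["role"] == ROLE_LIBRARY, "replicate"].max()) if len(t) else 0
        return cls(table=t[PLATE_MAP_COLUMNS], plate_format=plate_format, n_replicates=n_rep, seed=-1)


def build_screen_design(
    n_genes: int,
    plate_format: int = 384,
    n_replicates: int = 2,
    controls_per_plate: dict[str, int] | None = None,
    seed: int = 0,
) -> ScreenDesign:
    """Pack ``n_genes`` library genes onto the minimum number of plates.

    Control positions are drawn once (seeded) and shared by every plate;
    replicate ``r`` of a gene sits at the same well position on plate copy
    ``r``.  Plate ids are ``plate{i}r{r}``.
    """
    if n_genes < 1:
        raise DesignError("n_genes must be >= 1")
    if n_replicates < 1:
        raise DesignError("n_replicates must be >= 1")
    controls = dict(DEFAULT_CONTROLS if controls_per_plate is None else controls_per_plate)
    if controls.get(ROLE_RLUC, 0) < 4 or any(controls.get(r, 0) < 2 for r in (ROLE_TP53, ROLE_KIFC1)):
        raise DesignError("need >=4 R-LUC and >=2 of each positive control per plate")
    wells = well_names(plate_format)
    n_controls = sum(controls.values())
    n_lib_wells = len(wells) - n_controls
    if n_lib_wells < 1:
        raise DesignError(
            f"{n_controls} control wells do not leave library space on a {plate_format}-well plate"
        )

    rng = np.random.default_rng(seed)
    control_idx = rng.choice(len(wells), size=n_controls, replace=False)
    control_wells: list[tuple[str, str]] = []  # (well, role)
    i = 0
    for role in CONTROL_ROLES:
        for _ in range(controls.get(role, 0)):
            control_wells.append((wells[control_idx[i]], role))
            i += 1
    library_wells = [w for j, w in enumerate(wells) if j not in set(control_idx)]

    genes = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    n_plates = -(-n_genes // n_lib_wells)  # ceil

    rows = []
    for p in range(n_plates):
        plate_genes = genes[p * n_lib_wells : (p + 1) * n_lib_wells]
        for r in range(1, n_replicates + 1):
            plate_id = f"plate{p + 1:02d}r{r}"
            for well, role in control_wells:
                rows.append((plate_id, well, role, _CONTROL_GENE[role], r))
            for well, gene in zip(library_wells, plate_genes):
                rows.append((plate_id, well, ROLE_LIBRARY, gene, r))
            for well in library_wells[len(plate_genes) :]:
                rows.append((plate_id, well, ROLE_EMPTY, "", r))
    table = pd.DataFrame(rows, columns=PLATE_MAP_COLUMNS)
    design = ScreenDesign(table=table, plate_format=plate_format, n_replicates=n_replicates, seed=seed)
    design.validate()
    return design
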