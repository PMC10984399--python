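"""Experimental design handling for competitive-fitness assays.

The experiment assays evolved *C. elegans* populations against a GFP-marked
competitor in replicated blocks.  Each focal population is characterised by
its reproductive system (``wt`` selfing vs ``fog`` obligately outcrossing),
the temperature treatment it evolved under (20°C control vs 24°C elevated),
the isogenic line it was derived from (isoline 6, 8 or 9), the assay blocks
it was measured in, and the number of generations of experimental evolution
completed.  Ancestral populations (one ``wt`` and one ``fog`` per isoline)
are the divergence baselines and are assayed in every block of their isoline.

This module loads and validates the design table, counts the
population × block effect-size slots the pipeline will produce, and builds
the treatment-coded fixed-effects design matrix used by the meta-regression.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REPRO_TYPES = ("wt", "fog")
TREATMENTS = ("control_20C", "elevated_24C", "ancestral")
ISOLINES = ("6", "8", "9")

#: Column labels of the fixed-effects design matrix, in reporting order:
#: reference cell is isoline 6 / 20°C / wt.
DESIGN_MATRIX_COLUMNS = (
    "Intercept",
    "isoline 8",
    "isoline 9",
    "temperature 24",
    "repr.type fog",
    "generation nr",
    "isoline 8 × temperature 24",
    "isoline 9 × temperature 24",
    "isoline 8 × repr.type fog",
    "isoline 9 × repr.type fog",
    "temperature 24 × repr.type fog",
    "isoline 8 × temperature 24 × repr.type fog",
    "isoline 9 × temperature 24 × repr.type fog",
)

DESIGN_COLUMNS = ("type", "treatment", "isoline", "population", "blocks", "generation")


class DesignError(ValueError):
    """Raised when a design table violates the documented schema or invariants."""


@dataclass(frozen=True)
class DesignRecord:
    """One focal population with its covariates.

    ``generation`` is the number of generations of experimental evolution
    completed when the assayed sample was frozen; it is stored as 0 for
    ancestral populations, which serve as baselines rather than observations.
    """

    population_id: str
    repro_type: str
    treatment: str
    isoline: str
    blocks: tuple[str, ...]
    generation: int

    def __post_init__(self) -> None:
        if self.repro_type not in REPRO_TYPES:
            raise DesignError(
                f"unknown reproductive type {self.repro_type!r} for population "
                f"{self.population_id!r}; expected one of {REPRO_TYPES}"
            )
        if self.treatment not in TREATMENTS:
            raise DesignError(
                f"unknown treatment {self.treatment!r} for population "
                f"{self.population_id!r}; expected one of {TREATMENTS}"
            )
        if self.isoline not in ISOLINES:
            raise DesignError(
                f"unknown isoline {self.isoline!r} for population "
                f"{self.population_id!r}; expected one of {ISOLINES}"
            )
        if not self.blocks:
            raise DesignError(f"population {self.population_id!r} lists no blocks")
        if self.generation < 0:
            raise DesignError(f"negative generation for {self.population_id!r}")
        if not self.is_ancestral and len(self.blocks) not in (2, 4):
            raise DesignError(
                f"EE population {self.population_id!r} lists {len(self.blocks)} "
                "blocks; each evolved population is assayed in 2 or 4 blocks"
            )

    @property
    def is_ancestral(self) -> bool:
        return self.treatment == "ancestral"


@dataclass
class ExperimentDesign:
    """A validated collection of design records.

    ``synthesized_ancestors`` flags ancestral records that were not present in
    the loaded file and were created per isoline (one ``wt`` and one ``fog``,
    covering every block of that isoline).
    """

    records: list[DesignRecord]
    block_to_isoline: dict[str, str] = field(default_factory=dict)
    synthesized_ancestors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise DesignError("design contains no records")
        ids = [r.population_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise DesignError(f"duplicate population_id(s): {sorted(dupes)}")
        if not self.block_to_isoline:
            self.block_to_isoline = _infer_block_isolines(self.records)
        for rec in self.records:
            for b in rec.blocks:
                iso = self.block_to_isoline.get(b)
                if iso is None:
                    raise DesignError(
                        f"block {b!r} of population {rec.population_id!r} maps "
                        "to no isoline"
                    )
                if iso != rec.isoline:
                    raise DesignError(
                        f"population {rec.population_id!r} (isoline {rec.isoline})"
                        f" assayed in block {b!r} of isoline {iso}"
                    )
        # every block needs exactly one wt and one fog ancestor
        for block in self.blocks:
            for rt in REPRO_TYPES:
                anc = [
                    r for r in self.records
                    if r.is_ancestral and r.repro_type == rt and block in r.blocks
                ]
                if len(anc) != 1:
                    raise DesignError(
                        f"block {block!r} has {len(anc)} {rt} ancestral records; "
                        "expected exactly 1"
                    )

    @property
    def blocks(self) -> list[str]:
        return sorted(self.block_to_isoline)

    @property
    def ee_records(self) -> list[DesignRecord]:
        return [r for r in self.records if not r.is_ancestral]

    @property
    def ancestral_records(self) -> list[DesignRecord]:
        return [r for r in self.records if r.is_ancestral]

    def record(self, population_id: str) -> DesignRecord:
        for r in self.records:
            if r.population_id == population_id:
                return r
        raise KeyError(population_id)

    def ancestor_of(self, record: DesignRecord) -> DesignRecord:
        """The ancestral population matching ``record``'s isoline and repro type."""
        for r in self.ancestral_records:
            if r.isoline == record.isoline and r.repro_type == record.repro_type:
                return r
        raise DesignError(
            f"no {record.repro_type} ancestor for isoline {record.isoline}"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "type": [r.repro_type for r in self.records],
                "treatment": [r.treatment for r in self.records],
                "isoline": [r.isoline for r in self.records],
                "population": [r.population_id for r in self.records],
                "blocks": [";".join(r.blocks) for r in self.records],
                "generation": [r.generation for r in self.records],
            }
        )


def _infer_block_isolines(records: Iterable[DesignRecord]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for rec in records:
        for b in rec.blocks:
            prev = mapping.setdefault(b, rec.isoline)
            if prev != rec.isoline:
                raise DesignError(
                    f"block {b!r} is claimed by isolines {prev} and {rec.isoline}"
                )
    return mapping


def ancestral_id(repro_type: str, isoline: str) -> str:
    """Canonical population id for an ancestral baseline, e.g. ``ANC_wt_6``."""
    return f"ANC_{repro_type}_{isoline}"


def load_design(path: str | Path, synthesize_ancestors: bool = True) -> ExperimentDesign:
    """Load and validate a design table.

    The file is a comma-separated UTF-8 table with header columns
    ``type,treatment,isoline,population,blocks,generation``; the ``blocks``
    cell is a ``;``-separated list of block ids.  Ancestral records absent
    from the file are synthesized per isoline (flagged in
    ``synthesized_ancestors``) so that every block has its ``wt`` and ``fog``
    baselines.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, dtype=str)
    missing = [c for c in DESIGN_COLUMNS if c not in table.columns]
    if missing:
        raise DesignError(f"design file {path} is missing column(s): {missing}")
    if table.empty:
        raise DesignError(f"design file {path} contains a header but no records")

    records: list[DesignRecord] = []
    for idx, row in table.iterrows():
        try:
            records.append(
                DesignRecord(
                    population_id=str(row["population"]).strip(),
                    repro_type=str(row["type"]).strip().lower(),
                    treatment=str(row["treatment"]).strip(),
                    isoline=str(row["isoline"]).strip(),
                    blocks=tuple(
                        b.strip() for b in str(row["blocks"]).split(";") if b.strip()
                    ),
                    generation=int(row["generation"]),
                )
            )
        except (DesignError, ValueError) as exc:
            raise DesignError(f"row {idx + 2} of {path}: {exc}") from exc

    synthesized: list[str] = []
    if synthesize_ancestors:
        block_iso = _infer_block_isolines(records)
        for iso in sorted({r.isoline for r in records}):
            iso_blocks = tuple(sorted(b for b, i in block_iso.items() if i == iso))
            for rt in REPRO_TYPES:
                present = any(
                    r.is_ancestral and r.isoline == iso and r.repro_type == rt
                    for r in records
                )
                if not present:
                    pid = ancestral_id(rt, iso)
                    records.append(
                        DesignRecord(pid, rt, "ancestral", iso, iso_blocks, 0)
                    )
                    synthesized.append(pid)

    return ExperimentDesign(records, synthesized_ancestors=synthesized)


def write_design(design: ExperimentDesign, path: str | Path,
                 include_ancestors: bool = False) -> None:
    """Write the design back to its CSV dialect (EE records by default)."""
    frame = design.to_frame()
    if not include_ancestors:
        frame = frame[frame["treatment"] != "ancestral"]
    frame.to_csv(path, index=False)


def load_packaged_design() -> ExperimentDesign:
    """The packaged design fixture: 35 evolved populations in 8 blocks."""
    ref = importlib.resources.files("evofit.data") / "table1_design.csv"
    with importlib.resources.as_file(ref) as path:
        return load_design(path)


def count_effect_size_slots(design: ExperimentDesign) -> int:
    """Number of population × block effect sizes the pipeline will produce.

    Each evolved population contributes one divergence effect size per block
    it was assayed in (Σ over EE records of the number of blocks).
    """
    return sum(len(r.blocks) for r in design.ee_records)


@dataclass(frozen=True)
class CodingConfig:
    """Fixed-effect coding options.

    Treatment (dummy) coding against the reference cell isoline 6 / 20°C /
    ``wt``.  ``center_generation`` subtracts the mean generation number from
    the covariate column; the default keeps the raw generation number.
    """

    center_generation: bool = False


def build_design_matrix(
    effects: Sequence | pd.DataFrame,
    coding: CodingConfig | None = None,
    allow_rank_deficient: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Build the treatment-coded fixed-effects matrix for a set of effect sizes.

    ``effects`` is either a DataFrame with columns ``isoline``, ``treatment``,
    ``repro_type``, ``generation`` or a sequence of objects exposing those as
    attributes.  Returns the matrix together with its column labels (the 13
    coefficient rows of the reporting table: intercept, main effects of
    isoline 8/9, temperature 24 and fog, the generation covariate, all
    two-way interactions and both three-way interactions).

    Raises :class:`DesignError` naming the aliased columns if the matrix is
    rank deficient (e.g. a simulated design missing whole cells), unless
    ``allow_rank_deficient``.
    """
    if coding is None:
        coding = CodingConfig()
    if isinstance(effects, pd.DataFrame):
        iso = effects["isoline"].astype(str).to_numpy()
        trt = effects["treatment"].astype(str).to_numpy()
        rep = effects["repro_type"].astype(str).to_numpy()
        gen = effects["generation"].astype(float).to_numpy()
    else:
        iso = np.array([str(e.isoline) for e in effects])
        trt = np.array([str(e.treatment) for e in effects])
        rep = np.array([str(e.repro_type) for e in effects])
        gen = np.array([float(e.generation) for e in effects])

    bad_iso = sorted(set(iso) - set(ISOLINES))
    if bad_iso:
        raise DesignError(f"unknown isoline level(s) {bad_iso}")
    bad_trt = sorted(set(trt) - {"control_20C", "elevated_24C"})
    if bad_trt:
        raise DesignError(
            f"unknown treatment level(s) {bad_trt}; ancestral rows are "
            "baselines and do not enter the effect-size model"
        )
    bad_rep = sorted(set(rep) - set(REPRO_TYPES))
    if bad_rep:
        raise DesignError(f"unknown reproductive type(s) {bad_rep}")

    i8 = (iso == "8").astype(float)
    i9 = (iso == "9").astype(float)
    t24 = (trt == "elevated_24C").astype(float)
    fog = (rep == "fog").astype(float)
    g = gen - gen.mean() if coding.center_generation else gen

    cols = [
        np.ones_like(g),
        i8,
        i9,
        t24,
        fog,
        g,
        i8 * t24,
        i9 * t24,
        i8 * fog,
        i9 * fog,
        t24 * fog,
        i8 * t24 * fog,
        i9 * t24 * fog,
    ]
    X = np.column_stack(cols)
    labels = list(DESIGN_MATRIX_COLUMNS)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1] and not allow_rank_deficient:
        aliased = _aliased_columns(X, labels)
        raise DesignError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"aliased column(s): {aliased}"
        )
    return X, labels


def _aliased_columns(X: np.ndarray, labels: list[str]) -> list[str]:
    """Columns that do not increase the rank when added left to right."""
    aliased = []
    kept = np.empty((X.shape[0], 0))
    for j, lab in enumerate(labels):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) > kept.shape[1]:
            kept = cand
        else:
            aliased.append(lab)
    return aliased


def group_cells() -> list[dict[str, str]]:
    """The 12 isoline × treatment × reproductive-system cells, in display order."""
    cells = []
    for iso in ISOLINES:
        for rt in REPRO_TYPES:
            for trt in ("control_20C", "elevated_24C"):
                cells.append({"isoline": iso, "repro_type": rt, "treatment": trt})
    return cells
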