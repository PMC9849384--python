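"""Reading, validation, merging and classification of stability-variant datasets.

A variant is one amino-acid substitution in one protein chain, with an
experimentally measured change in unfolding free energy
``ddG = dG(mutant) - dG(wild-type)`` in kcal/mol.  Under this sign convention
destabilizing variants carry negative ddG.  Variants are partitioned into
three classes at the average experimental error of 0.5 kcal/mol:

* destabilizing: ddG <= -0.5
* neutral:       |ddG| < 0.5
* stabilizing:   ddG >= +0.5

The module reads tabular variant files (TSV/CSV with a configurable column
mapping), merges several datasets with key-level deduplication and overlap
accounting, derives thermodynamic reverse variants (ddG_MW = -ddG_WM), and
reports per-class composition tables.
"""

from __future__ import annotations

import csv
import enum
import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: the 20 canonical amino acids, one-letter codes, alphabetical
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: class boundary in kcal/mol (average experimental error on ddG)
NEUTRAL_BAND = 0.5

#: suffix appended to ``source_dataset`` when a record is a derived reverse variant
REVERSE_TAG = "-reverse"


class StabilityClass(str, enum.Enum):
    """Three-way partition of variants by experimental ddG."""

    DESTABILIZING = "destabilizing"
    NEUTRAL = "neutral"
    STABILIZING = "stabilizing"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: canonical row order used in composition and metric tables
CLASS_ORDER = [
    StabilityClass.DESTABILIZING,
    StabilityClass.NEUTRAL,
    StabilityClass.STABILIZING,
]


@dataclass(frozen=True)
class VariantRecord:
    """One amino-acid substitution with its experimental ddG.

    ``position`` is kept as a string because author numbering in PDB entries
    may carry insertion codes; purely numeric positions compare as their
    normalized string form.
    """

    source_dataset: str
    protein_id: str
    chain: str
    position: str
    wt_res: str
    mut_res: str
    ddg_exp: float

    def __post_init__(self) -> None:
        if self.wt_res not in AMINO_ACIDS:
            raise ValueError(f"unknown wild-type residue {self.wt_res!r}")
        if self.mut_res not in AMINO_ACIDS:
            raise ValueError(f"unknown mutant residue {self.mut_res!r}")
        if self.wt_res == self.mut_res:
            raise ValueError(
                f"wild-type and mutant residue are identical ({self.wt_res})"
            )
        if not math.isfinite(self.ddg_exp):
            raise ValueError(f"non-finite ddG {self.ddg_exp!r}")
        if len(self.chain) != 1:
            raise ValueError(f"chain id must be a single character, got {self.chain!r}")

    @property
    def key(self) -> tuple[str, str, str, str, str]:
        """Deduplication key: (protein, chain, position, wt, mut)."""
        return (self.protein_id, self.chain, self.position, self.wt_res, self.mut_res)

    @property
    def stability_class(self) -> StabilityClass:
        return classify_variant(self.ddg_exp)


@dataclass
class Dataset:
    """A named, ordered collection of variant records."""

    name: str
    records: list[VariantRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def keys(self) -> set[tuple]:
        return {r.key for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with one row per record plus the derived class column."""
        return pd.DataFrame(
            {
                "source_dataset": [r.source_dataset for r in self.records],
                "protein_id": [r.protein_id for r in self.records],
                "chain": [r.chain for r in self.records],
                "position": [r.position for r in self.records],
                "wt_res": [r.wt_res for r in self.records],
                "mut_res": [r.mut_res for r in self.records],
                "ddg_exp": [r.ddg_exp for r in self.records],
                "stability_class": [r.stability_class.value for r in self.records],
            }
        )


def classify_variant(ddg: float) -> StabilityClass:
    """Assign the three-way stability class of a ddG value (kcal/mol).

    The boundaries belong to the non-neutral classes: -0.5 is destabilizing
    and +0.5 is stabilizing; the neutral band is the open interval
    (-0.5, 0.5).
    """
    if not math.isfinite(ddg):
        raise ValueError(f"ddG must be finite, got {ddg!r}")
    if ddg <= -NEUTRAL_BAND:
        return StabilityClass.DESTABILIZING
    if ddg >= NEUTRAL_BAND:
        return StabilityClass.STABILIZING
    return StabilityClass.NEUTRAL


def make_reverse_variant(rec: VariantRecord) -> VariantRecord:
    """Thermodynamic mirror of a variant: residues swapped, ddG negated.

    Applying the operation twice returns the original record (the reverse
    tag on ``source_dataset`` toggles rather than accumulates).
    """
    if rec.source_dataset.endswith(REVERSE_TAG):
        source = rec.source_dataset[: -len(REVERSE_TAG)]
    else:
        source = rec.source_dataset + REVERSE_TAG
    return replace(
        rec,
        source_dataset=source,
        wt_res=rec.mut_res,
        mut_res=rec.wt_res,
        ddg_exp=-rec.ddg_exp,
    )


# ---------------------------------------------------------------------------
# Tabular input / output
# ---------------------------------------------------------------------------

#: default column mapping for variant tables (canonical field -> column name)
DEFAULT_DIALECT: dict[str, str] = {
    "protein_id": "protein_id",
    "chain": "chain",
    "position": "position",
    "wt_res": "wt_res",
    "mut_res": "mut_res",
    "ddg_exp": "ddg_exp",
}


def read_variant_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    name: str | None = None,
) -> Dataset:
    """Read a TSV/CSV variant table into a validated :class:`Dataset`.

    ``dialect`` maps the canonical field names (protein_id, chain, position,
    wt_res, mut_res, ddg_exp) to the column names used in the file.
    Malformed rows (bad residue codes, identical wt/mut, non-finite ddG) are
    skipped and counted in the log; an unreadable file or missing mapped
    column is fatal.
    """
    path = Path(path)
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    name = name or path.stem

    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep, dtype=str, comment="#")

    missing = [col for col in dialect.values() if col not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing mapped columns {missing}")

    records: list[VariantRecord] = []
    n_skipped = 0
    for idx, row in table.iterrows():
        try:
            records.append(
                VariantRecord(
                    source_dataset=name,
                    protein_id=str(row[dialect["protein_id"]]).strip(),
                    chain=str(row[dialect["chain"]]).strip(),
                    position=str(row[dialect["position"]]).strip(),
                    wt_res=str(row[dialect["wt_res"]]).strip().upper(),
                    mut_res=str(row[dialect["mut_res"]]).strip().upper(),
                    ddg_exp=float(row[dialect["ddg_exp"]]),
                )
            )
        except (ValueError, TypeError) as exc:
            n_skipped += 1
            logger.warning("%s row %s rejected: %s", path.name, idx, exc)
    if n_skipped:
        logger.info("%s: %d rows read, %d rejected", path.name, len(records), n_skipped)
    return Dataset(name=name, records=records)


def write_variant_table(ds: Dataset, path: str | Path) -> None:
    """Write a dataset as a TSV variant table (round-trips with the reader)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["protein_id", "chain", "position", "wt_res", "mut_res", "ddg_exp"]
        )
        for r in ds.records:
            writer.writerow(
                [r.protein_id, r.chain, r.position, r.wt_res, r.mut_res, repr(r.ddg_exp)]
            )


# ---------------------------------------------------------------------------
# Merging and composition
# ---------------------------------------------------------------------------


@dataclass
class MergeReport:
    """Bookkeeping for a dataset merge.

    ``overlaps`` maps tuples of dataset names (pairs, triples, ...) to the
    number of variant keys shared by all named datasets; ``collisions`` lists
    (key, kept_source, dropped_source) for every dropped duplicate, and
    ``ddg_conflicts`` the subset whose experimental ddG values disagreed by
    more than 0.5 kcal/mol.
    """

    overlaps: dict[tuple[str, ...], int] = field(default_factory=dict)
    collisions: list[tuple[tuple, str, str]] = field(default_factory=list)
    ddg_conflicts: list[tuple[tuple, float, float]] = field(default_factory=list)

    def overlap_frame(self) -> pd.DataFrame:
        rows = [
            {"datasets": "+".join(names), "shared_variants": n}
            for names, n in sorted(self.overlaps.items())
        ]
        return pd.DataFrame(rows, columns=["datasets", "shared_variants"])


def merge_datasets(
    datasets: Sequence[Dataset],
    priority: Sequence[str] | None = None,
    name: str = "merged",
) -> tuple[Dataset, MergeReport]:
    """Merge datasets with key-level deduplication and overlap accounting.

    Variants are deduplicated on (protein_id, chain, position, wt_res,
    mut_res).  On a key collision the record from the highest-priority
    dataset wins (``priority`` is an ordered list of dataset names, earliest
    wins; default is the given dataset order).  Colliding records whose ddG
    values differ by more than 0.5 kcal/mol are additionally reported as
    conflicts.  The report counts shared keys for every pair, triple, ... of
    input datasets, the counts one would print on a Venn diagram.
    """
    if not datasets:
        raise ValueError("merge_datasets needs at least one dataset")
    priority = list(priority) if priority is not None else [d.name for d in datasets]
    rank = {dsname: i for i, dsname in enumerate(priority)}

    report = MergeReport()
    key_sets = {d.name: d.keys() for d in datasets}
    names = [d.name for d in datasets]
    for size in range(2, len(names) + 1):
        for combo in itertools.combinations(names, size):
            shared = set.intersection(*(key_sets[n] for n in combo))
            report.overlaps[combo] = len(shared)

    chosen: dict[tuple, VariantRecord] = {}
    for ds in datasets:
        seen_in_ds: set[tuple] = set()
        for rec in ds.records:
            if rec.key in seen_in_ds:
                logger.warning("%s: duplicate key within dataset: %s", ds.name, rec.key)
                continue
            seen_in_ds.add(rec.key)
            held = chosen.get(rec.key)
            if held is None:
                chosen[rec.key] = rec
                continue
            if abs(held.ddg_exp - rec.ddg_exp) > NEUTRAL_BAND:
                report.ddg_conflicts.append((rec.key, held.ddg_exp, rec.ddg_exp))
                logger.warning(
                    "conflicting ddG on %s: %.3f (%s) vs %.3f (%s)",
                    rec.key, held.ddg_exp, held.source_dataset,
                    rec.ddg_exp, rec.source_dataset,
                )
            keep_new = rank.get(rec.source_dataset, len(rank)) < rank.get(
                held.source_dataset, len(rank)
            )
            if keep_new:
                chosen[rec.key] = rec
                report.collisions.append((rec.key, rec.source_dataset, held.source_dataset))
            else:
                report.collisions.append((rec.key, held.source_dataset, rec.source_dataset))

    merged = Dataset(name=name, records=list(chosen.values()))
    logger.info(
        "merged %s -> %d unique variants (%d collisions)",
        "+".join(names), len(merged), len(report.collisions),
    )
    return merged, report


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (display convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def class_composition(ds: Dataset) -> pd.DataFrame:
    """Per-class counts and integer percentages for one dataset.

    Returns one row with columns destabilizing / neutral / stabilizing
    (count and percent each) plus the total; counts always sum to the
    dataset size.
    """
    if len(ds) == 0:
        raise ValueError("class_composition of an empty dataset")
    counts = {cls: 0 for cls in CLASS_ORDER}
    for rec in ds.records:
        counts[rec.stability_class] += 1
    total = len(ds)
    row: dict[str, object] = {"dataset": ds.name, "total": total}
    for cls in CLASS_ORDER:
        row[cls.value] = counts[cls]
        row[f"{cls.value}_pct"] = _round_half_away(100.0 * counts[cls] / total)
    return pd.DataFrame([row])


def composition_table(datasets: Iterable[Dataset]) -> pd.DataFrame:
    """Stack :func:`class_composition` rows for several datasets."""
    return pd.concat([class_composition(d) for d in datasets], ignore_index=True)
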