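"""The seven residue-substitution features used by stability (ddG) predictors.

For a substitution W -> M at a given chain position the features are:

1. hydrophobicity difference  h(W) - h(M) on the Kyte-Doolittle scale
2. volume difference          V(M) - V(W) in cubic angstroms
3. conservation log-ratio     ln((CONS_W + eps) / (CONS_M + eps)), eps = 0.01
4. substitution-matrix score  B(W, M) from BLOSUM62 (symmetric in W, M)
5. relative solvent accessibility of the wild-type residue, in [0, 1]
6. Skolnick sequence-contact potential difference over a +/-2 residue window
7. Bastolla-Vendruscolo structural-contact potential difference over the
   5-angstrom neighborhood in the wild-type structure

Features 1-3, 6, 7 negate exactly when W and M are swapped; 4 and 5 are
swap-invariant, which is why a symmetric score cannot tell a stabilizing
substitution from the destabilizing reverse of the same pair.

All structural features are computed on the wild-type structure; no mutant
modelling is performed.  A variant whose structural neighborhood cannot be
resolved (residue absent, wild-type mismatch) is excluded and the reason
recorded, never silently zeroed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from Bio.Align import substitution_matrices
from Bio.PDB import PDBParser
from Bio.PDB.DSSP import make_dssp_dict
from Bio.PDB.Polypeptide import protein_letters_3to1
from Bio.PDB.SASA import ShrakeRupley

from .dataset_io import AMINO_ACIDS, VariantRecord

logger = logging.getLogger(__name__)

#: default pseudo-count for conservation frequencies
EPSILON = 0.01

#: default structural-neighborhood radius in angstroms
NEIGHBOR_RADIUS = 5.0

#: canonical feature-column names, in report order
FEATURE_NAMES = [
    "hydrophobicity_diff",
    "volume_diff",
    "cons_log_ratio",
    "blosum_score",
    "accessibility",
    "skolnick_diff",
    "bv_diff",
]

#: features that change sign when wild-type and mutant are swapped
ANTISYMMETRIC_FEATURES = [
    "hydrophobicity_diff",
    "volume_diff",
    "cons_log_ratio",
    "skolnick_diff",
    "bv_diff",
]

#: features invariant under the swap (the symmetric scores)
SYMMETRIC_FEATURES = ["blosum_score", "accessibility"]

# Kyte-Doolittle hydropathy index (dimensionless).
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

# Residue volumes in cubic angstroms (Zamyatnin's crystallographic set).
RESIDUE_VOLUME: dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
}

# Theoretical maximum accessible surface areas (Tien et al. theoretical set),
# used to normalize absolute ASA into relative accessibility.
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0, "E": 223.0,
    "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0, "L": 201.0, "K": 236.0,
    "M": 224.0, "F": 240.0, "P": 159.0, "S": 155.0, "T": 172.0, "W": 285.0,
    "Y": 263.0, "V": 174.0,
}


class VariantExclusion(Exception):
    """A variant that must be dropped from the analysis, with a reason.

    Mirrors the curation rule that variants with unresolvable structural
    neighborhoods are excluded rather than imputed.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def _check_scale(scale: Mapping[str, float], what: str) -> None:
    missing = [aa for aa in AMINO_ACIDS if aa not in scale]
    if missing:
        raise ValueError(f"{what} is missing amino acids {missing}")


# ---------------------------------------------------------------------------
# Matrix and potential resources
# ---------------------------------------------------------------------------


def load_blosum62() -> substitution_matrices.Array:
    """The standard BLOSUM62 substitution matrix (symmetric, integer-valued)."""
    return substitution_matrices.load("BLOSUM62")


def read_substitution_matrix(path: str | Path) -> substitution_matrices.Array:
    """Read a substitution matrix in the standard NCBI text format."""
    return substitution_matrices.read(str(path))


@dataclass
class PairPotential:
    """A symmetric 20x20 statistical contact potential.

    ``role`` records whether the potential scores sequence-window contacts
    (Skolnick) or structural contacts within a radius (Bastolla-Vendruscolo);
    it does not change the lookup semantics.
    """

    values: pd.DataFrame
    role: Literal["sequence", "structural"] = "sequence"

    def __post_init__(self) -> None:
        aas = list(AMINO_ACIDS)
        missing = [a for a in aas if a not in self.values.index or a not in self.values.columns]
        if missing:
            raise ValueError(f"pair potential incomplete: missing {missing}")
        self.values = self.values.loc[aas, aas].astype(float)
        if not np.allclose(self.values.to_numpy(), self.values.to_numpy().T):
            raise ValueError("pair potential must be symmetric")

    def __call__(self, a: str, b: str) -> float:
        try:
            return float(self.values.at[a, b])
        except KeyError as exc:
            raise KeyError(f"pair potential has no entry for ({a}, {b})") from exc

    @classmethod
    def read_tsv(cls, path: str | Path, role: str = "sequence") -> "PairPotential":
        """Read a tab-delimited 20x20 matrix with residue row/column labels."""
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=frame, role=role)  # type: ignore[arg-type]

    def write_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Conservation profiles
# ---------------------------------------------------------------------------


@dataclass
class ConservationProfile:
    """Per-position amino-acid frequencies from a multiple-sequence alignment.

    ``freqs`` is indexed by position label (author numbering as strings) with
    one column per amino acid; frequencies lie in [0, 1] and may sum to less
    than one when the alignment column contains gaps.  ``epsilon`` is the
    pseudo-count added to both frequencies in the conservation log-ratio.
    """

    freqs: pd.DataFrame
    epsilon: float = EPSILON

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        missing = [aa for aa in AMINO_ACIDS if aa not in self.freqs.columns]
        if missing:
            raise ValueError(f"profile missing amino-acid columns {missing}")
        self.freqs = self.freqs[list(AMINO_ACIDS)].astype(float)
        self.freqs.index = self.freqs.index.map(str)
        sums = self.freqs.sum(axis=1)
        if (self.freqs.to_numpy() < -1e-9).any() or (sums > 1.0 + 1e-6).any():
            raise ValueError("profile frequencies must lie in [0, 1] and sum to <= 1")

    def frequency(self, pos: str | int, res: str) -> float:
        return float(self.freqs.at[str(pos), res])

    def __contains__(self, pos: object) -> bool:
        return str(pos) in self.freqs.index

    @classmethod
    def read_tsv(cls, path: str | Path, epsilon: float = EPSILON) -> "ConservationProfile":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame.index = frame.index.map(str)
        return cls(freqs=frame, epsilon=epsilon)

    def write_tsv(self, path: str | Path) -> None:
        out = self.freqs.copy()
        out.index.name = "position"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------


@dataclass
class _ResidueData:
    one_letter: str
    coords: np.ndarray  # (n_heavy_atoms, 3)


@dataclass
class StructureModel:
    """Heavy-atom coordinates of a protein structure, keyed by chain/position.

    Built from a PDB coordinate file; hydrogens, waters and non-standard
    residues are ignored.  Holds the underlying Biopython entity so that
    solvent accessibility can be computed on demand.
    """

    name: str
    residues: dict[tuple[str, str], _ResidueData] = field(default_factory=dict)
    chain_order: dict[str, list[str]] = field(default_factory=dict)
    _entity: object | None = None
    _sasa: dict[tuple[str, str], float] | None = None

    @classmethod
    def from_pdb(cls, path: str | Path, name: str | None = None) -> "StructureModel":
        path = Path(path)
        parser = PDBParser(QUIET=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            entity = parser.get_structure(name or path.stem, str(path))
        model = cls(name=name or path.stem, _entity=entity)
        first = next(entity.get_models())
        for chain in first:
            order: list[str] = []
            for res in chain:
                hetflag, resseq, icode = res.get_id()
                if hetflag.strip():
                    continue
                one = protein_letters_3to1.get(res.get_resname().upper())
                if one is None or one not in AMINO_ACIDS:
                    continue
                pos = f"{resseq}{icode.strip()}"
                coords = np.array(
                    [a.coord for a in res.get_atoms() if a.element != "H"], dtype=float
                )
                if coords.size == 0 or not np.isfinite(coords).all():
                    continue
                model.residues[(chain.id, pos)] = _ResidueData(one, coords)
                order.append(pos)
            if order:
                model.chain_order[chain.id] = order
        return model

    def residue(self, chain: str, pos: str | int) -> _ResidueData:
        try:
            return self.residues[(chain, str(pos))]
        except KeyError:
            raise VariantExclusion(
                f"3D neighbors: residue {chain}/{pos} absent from structure {self.name}"
            ) from None

    def chain_sequence(self, chain: str) -> str:
        """One-letter sequence of a chain in author-numbering order."""
        try:
            order = self.chain_order[chain]
        except KeyError:
            raise VariantExclusion(f"3D neighbors: chain {chain} absent from {self.name}") from None
        return "".join(self.residues[(chain, p)].one_letter for p in order)

    def position_index(self, chain: str, pos: str | int) -> int:
        """0-based index of an author position within its chain sequence."""
        order = self.chain_order.get(chain, [])
        try:
            return order.index(str(pos))
        except ValueError:
            raise VariantExclusion(
                f"3D neighbors: residue {chain}/{pos} absent from structure {self.name}"
            ) from None

    def neighbors_within(
        self,
        chain: str,
        pos: str | int,
        radius: float = NEIGHBOR_RADIUS,
        mode: Literal["heavy", "cb", "ca"] = "heavy",
    ) -> list[tuple[str, str]]:
        """Residues whose minimal inter-residue distance is within ``radius``.

        The default metric is the minimum over all heavy-atom pairs; "cb" and
        "ca" use a single representative atom per residue (the last/first
        backbone-adjacent atom available).  The mutated residue itself is
        never part of its own neighborhood.
        """
        center = self.residue(chain, pos)
        keys, all_coords, owner = [], [], []
        for key, rd in self.residues.items():
            if key == (chain, str(pos)):
                continue
            coords = self._representative_coords(rd, mode)
            keys.append(key)
            all_coords.append(coords)
            owner.extend([len(keys) - 1] * len(coords))
        if not keys:
            return []
        stacked = np.vstack(all_coords)
        tree = cKDTree(stacked)
        center_coords = self._representative_coords(center, mode)
        hit_atoms = tree.query_ball_point(center_coords, r=radius)
        hit_res = sorted({owner[i] for hits in hit_atoms for i in hits})
        return [keys[i] for i in hit_res]

    @staticmethod
    def _representative_coords(rd: _ResidueData, mode: str) -> np.ndarray:
        if mode == "heavy":
            return rd.coords
        # single-atom modes fall back to the first atom when the chosen one
        # is not distinguishable from the stored heavy-atom list
        idx = min(len(rd.coords) - 1, 4 if mode == "cb" else 1)
        return rd.coords[idx : idx + 1]

    def solvent_accessibility(self, chain: str, pos: str | int) -> float:
        """Absolute accessible surface area (A^2) via the Shrake-Rupley method.

        Used when no precomputed DSSP output is available; computed once per
        structure and cached.
        """
        if self._sasa is None:
            if self._entity is None:
                raise VariantExclusion(
                    f"3D neighbors: no coordinate entity for {self.name}"
                )
            sr = ShrakeRupley()
            first = next(self._entity.get_models())
            sr.compute(first, level="R")
            self._sasa = {}
            for ch in first:
                for res in ch:
                    hetflag, resseq, icode = res.get_id()
                    if hetflag.strip():
                        continue
                    self._sasa[(ch.id, f"{resseq}{icode.strip()}")] = float(res.sasa)
        try:
            return self._sasa[(chain, str(pos))]
        except KeyError:
            raise VariantExclusion(
                f"3D neighbors: residue {chain}/{pos} absent from structure {self.name}"
            ) from None


# ---------------------------------------------------------------------------
# The seven features
# ---------------------------------------------------------------------------


def hydrophobicity_difference(
    wt: str, mut: str, scale: Mapping[str, float] | None = None, *, wt_minus_mut: bool = True
) -> float:
    """Hydropathy difference between the two residues, default h(wt) - h(mut)."""
    scale = scale if scale is not None else KYTE_DOOLITTLE
    for aa in (wt, mut):
        if aa not in scale:
            raise KeyError(f"residue {aa!r} missing from hydrophobicity scale")
    diff = scale[wt] - scale[mut]
    return diff if wt_minus_mut else -diff


def volume_difference(
    wt: str, mut: str, scale: Mapping[str, float] | None = None, *, mut_minus_wt: bool = True
) -> float:
    """Residue-volume difference in A^3, default V(mut) - V(wt).

    Oriented so that a positive value means the mutant residue is larger
    than the wild-type, the disruptive direction.
    """
    scale = scale if scale is not None else RESIDUE_VOLUME
    for aa in (wt, mut):
        if aa not in scale:
            raise KeyError(f"residue {aa!r} missing from volume scale")
    diff = scale[mut] - scale[wt]
    return diff if mut_minus_wt else -diff


def blosum_score(wt: str, mut: str, matrix=None) -> float:
    """Substitution-matrix score B(wt, mut); symmetric in its arguments."""
    matrix = matrix if matrix is not None else load_blosum62()
    try:
        return float(matrix[wt, mut])
    except (KeyError, IndexError) as exc:
        raise KeyError(f"substitution matrix has no entry for ({wt}, {mut})") from exc


def conservation_log_ratio(
    profile: ConservationProfile, pos: str | int, wt: str, mut: str
) -> float:
    """Natural log of (CONS_wt + eps) / (CONS_mut + eps) at one position.

    Positive when the wild-type residue is the more conserved one, i.e. when
    the substitution moves to a less conserved residue.  Returns NaN (and
    logs) when the position is absent from the profile.
    """
    if pos not in profile:
        logger.warning("position %s absent from conservation profile", pos)
        return float("nan")
    cw = profile.frequency(pos, wt)
    cm = profile.frequency(pos, mut)
    eps = profile.epsilon
    return math.log((cw + eps) / (cm + eps))


def relative_accessibility(
    source,
    chain: str,
    pos: str | int,
    max_asa_table: Mapping[str, float] | None = None,
    *,
    residue_type: str | None = None,
) -> float:
    """Relative solvent accessibility of a residue, clipped to [0, 1].

    ``source`` is either a :class:`StructureModel` (accessibility computed
    internally with the Shrake-Rupley method) or the dictionary returned by
    parsing a DSSP output file with :func:`read_dssp`.  The absolute
    accessible surface area is divided by the residue-type theoretical
    maximum.
    """
    max_asa_table = max_asa_table if max_asa_table is not None else MAX_ASA
    if isinstance(source, StructureModel):
        res = source.residue(chain, pos)
        asa = source.solvent_accessibility(chain, pos)
        res_type = residue_type or res.one_letter
    elif isinstance(source, Mapping):
        try:
            asa, res_type_found = source[(chain, str(pos))]
        except KeyError:
            raise VariantExclusion(
                f"3D neighbors: residue {chain}/{pos} absent from DSSP output"
            ) from None
        res_type = residue_type or res_type_found
    else:
        raise TypeError(f"cannot compute accessibility from {type(source)!r}")
    if res_type not in max_asa_table:
        raise KeyError(f"no maximum ASA for residue type {res_type!r}")
    return float(np.clip(asa / max_asa_table[res_type], 0.0, 1.0))


def read_dssp(path: str | Path) -> dict[tuple[str, str], tuple[float, str]]:
    """Parse a DSSP output file into {(chain, position): (absolute ASA, residue)}."""
    dssp_dict, _ = make_dssp_dict(str(path))
    out: dict[tuple[str, str], tuple[float, str]] = {}
    for (chain, (_, resseq, icode)), fields in dssp_dict.items():
        aa, acc = fields[0], fields[2]
        out[(chain, f"{resseq}{icode.strip()}")] = (float(acc), aa)
    return out


#: window offsets for the Skolnick sequence-contact sum; the pairwise
#: potential has no self-interaction term, so offset 0 is excluded by default
SKOLNICK_OFFSETS = (-2, -1, 1, 2)


def skolnick_potential_diff(
    sequence: str,
    pos_index: int,
    wt: str,
    mut: str,
    potential: PairPotential,
    offsets: Sequence[int] = SKOLNICK_OFFSETS,
) -> float:
    """Sequence-window contact-energy difference sum_i sk(wt, a_i) - sk(mut, a_i).

    Neighbors ``a_i`` are taken from the wild-type sequence at the given
    offsets around ``pos_index`` (0-based); offsets that fall outside the
    sequence are truncated at the termini.
    """
    if not 0 <= pos_index < len(sequence):
        raise IndexError(f"position index {pos_index} outside sequence of length {len(sequence)}")
    total = 0.0
    for off in offsets:
        j = pos_index + off
        if j < 0 or j >= len(sequence):
            continue
        neighbor = sequence[j] if off != 0 else wt
        total += potential(wt, neighbor) - potential(mut, neighbor)
    return total


def bastolla_vendruscolo_diff(
    structure: StructureModel,
    chain: str,
    pos: str | int,
    wt: str,
    mut: str,
    potential: PairPotential,
    radius: float = NEIGHBOR_RADIUS,
    mode: Literal["heavy", "cb", "ca"] = "heavy",
) -> float:
    """Structural contact-energy difference sum over the radius neighborhood.

    The neighborhood is every residue (other than the mutated one) whose
    minimal heavy-atom distance to the mutated residue is within ``radius``
    angstroms; an empty neighborhood gives 0.
    """
    neighbors = structure.neighbors_within(chain, pos, radius=radius, mode=mode)
    total = 0.0
    for key in neighbors:
        a_i = structure.residues[key].one_letter
        total += potential(wt, a_i) - potential(mut, a_i)
    return total


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


@dataclass
class FeatureVector:
    """The seven named feature values for one variant."""

    hydrophobicity_diff: float
    volume_diff: float
    cons_log_ratio: float
    blosum_score: float
    accessibility: float
    skolnick_diff: float
    bv_diff: float

    def __post_init__(self) -> None:
        if not (math.isnan(self.accessibility) or 0.0 <= self.accessibility <= 1.0):
            raise ValueError(f"accessibility {self.accessibility} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


@dataclass
class ResourceBundle:
    """Everything needed to evaluate the seven features for a set of proteins.

    ``structures`` and ``profiles`` are keyed by protein id; DSSP
    dictionaries (from :func:`read_dssp`) are optional per protein and take
    precedence over the internal accessibility computation.
    """

    hydro_scale: Mapping[str, float] = field(default_factory=lambda: dict(KYTE_DOOLITTLE))
    volume_scale: Mapping[str, float] = field(default_factory=lambda: dict(RESIDUE_VOLUME))
    max_asa: Mapping[str, float] = field(default_factory=lambda: dict(MAX_ASA))
    blosum: object | None = None
    skolnick: PairPotential | None = None
    bv: PairPotential | None = None
    structures: dict[str, StructureModel] = field(default_factory=dict)
    profiles: dict[str, ConservationProfile] = field(default_factory=dict)
    dssp: dict[str, Mapping] = field(default_factory=dict)
    radius: float = NEIGHBOR_RADIUS
    neighbor_mode: Literal["heavy", "cb", "ca"] = "heavy"
    skolnick_offsets: Sequence[int] = SKOLNICK_OFFSETS

    def __post_init__(self) -> None:
        _check_scale(self.hydro_scale, "hydrophobicity scale")
        _check_scale(self.volume_scale, "volume scale")
        _check_scale(self.max_asa, "max-ASA table")
        if self.blosum is None:
            self.blosum = load_blosum62()


def compute_feature_vector(rec: VariantRecord, resources: ResourceBundle) -> FeatureVector:
    """Evaluate all seven features for one variant.

    Raises :class:`VariantExclusion` (reason "3D neighbors") when the
    structural neighborhood cannot be resolved: the structure is missing,
    the residue is absent, or the structure's residue type contradicts the
    table's wild-type residue.  Non-structural resources that are missing
    yield NaN for the affected feature only.
    """
    if resources.skolnick is None or resources.bv is None:
        raise ValueError("resource bundle lacks the Skolnick and/or BV potentials")
    structure = resources.structures.get(rec.protein_id)
    if structure is None:
        raise VariantExclusion(f"3D neighbors: no structure for {rec.protein_id}")
    res = structure.residue(rec.chain, rec.position)
    if res.one_letter != rec.wt_res:
        raise VariantExclusion(
            f"3D neighbors: structure has {res.one_letter} at "
            f"{rec.chain}/{rec.position}, table says {rec.wt_res}"
        )

    profile = resources.profiles.get(rec.protein_id)
    if profile is None:
        logger.warning("no conservation profile for %s", rec.protein_id)
        cons = float("nan")
    else:
        cons = conservation_log_ratio(profile, rec.position, rec.wt_res, rec.mut_res)

    dssp = resources.dssp.get(rec.protein_id)
    acc_source = dssp if dssp is not None else structure
    acc = relative_accessibility(
        acc_source, rec.chain, rec.position, resources.max_asa, residue_type=rec.wt_res
    )

    seq = structure.chain_sequence(rec.chain)
    idx = structure.position_index(rec.chain, rec.position)

    return FeatureVector(
        hydrophobicity_diff=hydrophobicity_difference(rec.wt_res, rec.mut_res, resources.hydro_scale),
        volume_diff=volume_difference(rec.wt_res, rec.mut_res, resources.volume_scale),
        cons_log_ratio=cons,
        blosum_score=blosum_score(rec.wt_res, rec.mut_res, resources.blosum),
        accessibility=acc,
        skolnick_diff=skolnick_potential_diff(
            seq, idx, rec.wt_res, rec.mut_res, resources.skolnick, resources.skolnick_offsets
        ),
        bv_diff=bastolla_vendruscolo_diff(
            structure, rec.chain, rec.position, rec.wt_res, rec.mut_res,
            resources.bv, resources.radius, resources.neighbor_mode,
        ),
    )


def compute_feature_table(
    records: Sequence[VariantRecord], resources: ResourceBundle
) -> tuple[pd.DataFrame, list[tuple[VariantRecord, str]]]:
    """Batch feature computation; returns (feature table, exclusions).

    The table has the variant key columns, ddg_exp, the stability class and
    the seven feature columns; excluded variants are returned separately
    with their reasons and logged.
    """
    rows, excluded = [], []
    for rec in records:
        try:
            vec = compute_feature_vector(rec, resources)
        except VariantExclusion as exc:
            excluded.append((rec, exc.reason))
            logger.info("excluded %s: %s", rec.key, exc.reason)
            continue
        row = {
            "source_dataset": rec.source_dataset,
            "protein_id": rec.protein_id,
            "chain": rec.chain,
            "position": rec.position,
            "wt_res": rec.wt_res,
            "mut_res": rec.mut_res,
            "ddg_exp": rec.ddg_exp,
            "stability_class": rec.stability_class.value,
        }
        row.update(vec.as_dict())
        rows.append(row)
    logger.info("feature table: %d variants, %d excluded", len(rows), len(excluded))
    columns = [
        "source_dataset", "protein_id", "chain", "position", "wt_res", "mut_res",
        "ddg_exp", "stability_class", *FEATURE_NAMES,
    ]
    return pd.DataFrame(rows, columns=columns), excluded
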