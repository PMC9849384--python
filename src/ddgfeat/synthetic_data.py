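"""Synthetic study inputs with controlled statistical structure.

Real stability-variant studies need variant tables, PDB structures, DSSP
output, conservation profiles and 20x20 potential matrices.  Every
generator here emits the same on-disk formats the pipeline consumes, so the
whole analysis is exercisable without downloads:

* variant tables with the empirical class imbalance (55/30/15
  destabilizing/neutral/stabilizing) and per-class truncated-Gaussian ddG
  distributions whose pooled mode sits near -1 kcal/mol,
* feature vectors engineered to hit target per-class Pearson correlations
  with ddG in expectation,
* a swap-symmetric matrix score, the mechanism by which a symmetric
  substitution matrix cannot separate direct from reverse variants,
* toy peptide structures (ideal helix or extended chain) written as PDB,
* single-sequence conservation profiles at a chosen conservation level,
* random symmetric substitution/potential matrices in their file formats.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from Bio.Align import substitution_matrices
from Bio.PDB import PDBIO, StructureBuilder
from Bio.PDB.Polypeptide import protein_letters_3to1

from .dataset_io import AMINO_ACIDS, Dataset, StabilityClass, VariantRecord, classify_variant
from .features import ConservationProfile, PairPotential, StructureModel

protein_letters_1to3 = {v: k for k, v in protein_letters_3to1.items()}

#: empirical class proportions of the merged benchmark corpus
DEFAULT_PROPORTIONS = (0.55, 0.30, 0.15)

#: per-class (location, scale) of the truncated-Gaussian ddG distributions,
#: kcal/mol; destabilizing is truncated to (-inf, -0.5], neutral to
#: (-0.5, 0.5), stabilizing to [0.5, inf).  The neutral scale is wide so the
#: band is filled nearly uniformly; the destabilizing bulk then dominates
#: the pooled histogram, reproducing the unimodal shape with mode near
#: -1 kcal/mol seen in the benchmark datasets.
DEFAULT_DDG_PARAMS = {
    StabilityClass.DESTABILIZING: (-1.0, 0.9),
    StabilityClass.NEUTRAL: (0.0, 1.5),
    StabilityClass.STABILIZING: (0.8, 0.9),
}


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic variant-table generator."""

    n_variants: int = 4428
    class_proportions: tuple[float, float, float] = DEFAULT_PROPORTIONS
    ddg_params: dict = field(default_factory=lambda: dict(DEFAULT_DDG_PARAMS))
    n_proteins: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.class_proportions), 1.0, abs_tol=1e-9):
            raise ValueError("class proportions must sum to 1")
        if any(p < 0 for p in self.class_proportions):
            raise ValueError("class proportions must be non-negative")
        for cls, (_, scale) in self.ddg_params.items():
            if scale <= 0:
                raise ValueError(f"ddG scale for {cls} must be positive")


_CLASS_BANDS = {
    StabilityClass.DESTABILIZING: (-np.inf, -0.5),
    StabilityClass.NEUTRAL: (-0.5, 0.5),
    StabilityClass.STABILIZING: (0.5, np.inf),
}


def _sample_class_ddg(
    cls: StabilityClass, n: int, params: dict, rng: np.random.Generator
) -> np.ndarray:
    loc, scale = params[cls]
    lo, hi = _CLASS_BANDS[cls]
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)


def generate_variant_dataset(spec: GeneratorSpec) -> tuple[Dataset, pd.DataFrame]:
    """Draw a synthetic variant table with the configured class structure.

    Class membership is multinomial with the spec proportions; within each
    class, ddG is a truncated Gaussian confined to the class band, so every
    drawn variant classifies into the class it was drawn for.  Returns the
    dataset and a ground-truth table recording the generating class and
    parameters per variant.
    """
    rng = np.random.default_rng(spec.seed)
    labels = rng.choice(3, size=spec.n_variants, p=spec.class_proportions)
    classes = [list(_CLASS_BANDS)[i] for i in labels]

    ddg = np.empty(spec.n_variants)
    for i, cls in enumerate(_CLASS_BANDS):
        mask = labels == i
        ddg[mask] = _sample_class_ddg(cls, int(mask.sum()), spec.ddg_params, rng)

    aas = np.array(list(AMINO_ACIDS))
    proteins = [f"S{i:03d}" for i in range(spec.n_proteins)]
    records, used_keys = [], set()
    truth_rows = []
    for i in range(spec.n_variants):
        while True:
            pid = proteins[int(rng.integers(spec.n_proteins))]
            pos = str(int(rng.integers(1, 400)))
            wt, mut = rng.choice(aas, size=2, replace=False)
            key = (pid, "A", pos, wt, mut)
            if key not in used_keys:
                used_keys.add(key)
                break
        rec = VariantRecord(
            source_dataset="synthetic",
            protein_id=pid, chain="A", position=pos,
            wt_res=str(wt), mut_res=str(mut), ddg_exp=float(ddg[i]),
        )
        records.append(rec)
        loc, scale = spec.ddg_params[classes[i]]
        truth_rows.append(
            {"protein_id": pid, "chain": "A", "position": pos,
             "wt_res": str(wt), "mut_res": str(mut), "ddg_exp": float(ddg[i]),
             "true_class": classes[i].value, "ddg_loc": loc, "ddg_scale": scale}
        )
    return Dataset(name="synthetic", records=records), pd.DataFrame(truth_rows)


def generate_correlated_feature(
    ddg: Sequence[float],
    classes: Sequence,
    target_rho_per_class: dict,
    seed: int = 0,
) -> np.ndarray:
    """A feature hitting a target Pearson correlation with ddG inside each class.

    Within class c the feature is rho_c * z_c + sqrt(1 - rho_c^2) * eps with
    z_c the within-class standardized ddG and eps standard normal, so the
    within-class correlation equals rho_c in expectation and the feature's
    class means are all zero.  The pooled correlation is therefore
    attenuated by the between-class ddG spread:
    rho_pooled = sum_c w_c rho_c sigma_c / sigma_pooled.
    """
    ddg = np.asarray(ddg, dtype=float)
    cls = np.asarray([c.value if isinstance(c, StabilityClass) else str(c) for c in classes])
    rng = np.random.default_rng(seed)
    out = np.empty_like(ddg)
    for c, rho in target_rho_per_class.items():
        cval = c.value if isinstance(c, StabilityClass) else str(c)
        if not -1 < rho < 1:
            raise ValueError(f"target rho for {cval} must be in (-1, 1)")
        mask = cls == cval
        n = int(mask.sum())
        if n < 3:
            raise ValueError(f"class {cval} has fewer than 3 members")
        z = (ddg[mask] - ddg[mask].mean()) / ddg[mask].std()
        out[mask] = rho * z + math.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    return out


def expected_balanced_correlation(
    ddg: Sequence[float], classes: Sequence, target_rho_per_class: dict
) -> float:
    """Closed-form pooled correlation of a class-targeted feature on balanced data.

    With unit-variance, zero-mean-per-class features the balanced pooled
    correlation is sum_c rho_c sigma_c / (k * sigma_bal), where sigma_c are
    within-class ddG standard deviations and sigma_bal the pooled balanced
    ddG standard deviation (equal class weights).
    """
    ddg = np.asarray(ddg, dtype=float)
    cls = np.asarray([c.value if isinstance(c, StabilityClass) else str(c) for c in classes])
    items = [(c.value if isinstance(c, StabilityClass) else str(c), rho)
             for c, rho in target_rho_per_class.items()]
    k = len(items)
    sigmas, mus, cov = [], [], 0.0
    for cval, rho in items:
        vals = ddg[cls == cval]
        sigmas.append(vals.std())
        mus.append(vals.mean())
        cov += rho * vals.std() / k
    var_bal = float(np.mean(np.square(sigmas)) + np.var(mus))
    return cov / math.sqrt(var_bal)


def generate_symmetric_score_feature(
    records: Sequence[VariantRecord], seed: int = 0, scale: float = 1.0
) -> np.ndarray:
    """Score each variant with a random swap-symmetric 20x20 matrix.

    The score of W->M equals the score of M->W, emulating the behaviour of a
    substitution matrix: on paired direct/reverse data the score carries no
    information about the sign of ddG, so destabilizing-vs-stabilizing
    discrimination collapses to AUC 0.5.
    """
    rng = np.random.default_rng(seed)
    raw = rng.normal(scale=scale, size=(20, 20))
    sym = (raw + raw.T) / 2.0
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    return np.array([sym[index[r.wt_res], index[r.mut_res]] for r in records])


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------


@dataclass
class ToyStructureSpec:
    """A small peptide with deterministic geometry for structural features."""

    sequence: str
    mode: Literal["ideal-helix", "extended"] = "extended"
    chain: str = "A"
    name: str = "TOY"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = [aa for aa in self.sequence if aa not in AMINO_ACIDS]
        if bad:
            raise ValueError(f"unknown residues in sequence: {bad}")


# local heavy-atom template (N, CA, C, O, CB offsets from CA), used for every
# residue; geometrically simplified but deterministic and collision-free
_ATOM_TEMPLATE = {
    "N": np.array([-1.20, 0.80, 0.00]),
    "CA": np.array([0.00, 0.00, 0.00]),
    "C": np.array([1.20, 0.80, 0.00]),
    "O": np.array([1.20, 2.03, 0.00]),
    "CB": np.array([0.00, -0.77, 1.25]),
}


def _ca_positions(spec: ToyStructureSpec) -> np.ndarray:
    n = len(spec.sequence)
    if spec.mode == "extended":
        return np.column_stack(
            [3.8 * np.arange(n), 0.4 * (np.arange(n) % 2), np.zeros(n)]
        )
    # ideal alpha-helix CA trace: radius 2.3 A, rise 1.5 A, 100 deg/residue
    theta = np.deg2rad(100.0) * np.arange(n)
    return np.column_stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * np.arange(n)]
    )


def generate_toy_structure(spec: ToyStructureSpec) -> tuple[StructureModel, str]:
    """Build a toy peptide and return (StructureModel, PDB text).

    The PDB text parses back to an equivalent model; residue neighborhoods
    under a fixed radius are deterministic functions of the spec.
    """
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure(spec.name)
    builder.init_model(0)
    builder.init_chain(spec.chain)
    builder.init_seg("    ")
    ca = _ca_positions(spec)
    serial = 1
    for i, aa in enumerate(spec.sequence):
        builder.init_residue(protein_letters_1to3[aa], " ", i + 1, " ")
        atoms = dict(_ATOM_TEMPLATE)
        if aa == "G":
            atoms = {k: v for k, v in atoms.items() if k != "CB"}
        for atom_name, offset in atoms.items():
            builder.init_atom(
                atom_name, (ca[i] + offset).astype(float), 0.0, 1.0, " ",
                atom_name.ljust(3), serial, element=atom_name[0],
            )
            serial += 1
    structure = builder.get_structure()

    io = PDBIO()
    io.set_structure(structure)
    import io as _io

    buf = _io.StringIO()
    io.save(buf)
    pdb_text = buf.getvalue()

    model = _model_from_entity(structure, spec.name)
    return model, pdb_text


def _model_from_entity(entity, name: str) -> StructureModel:
    model = StructureModel(name=name, _entity=entity)
    first = next(entity.get_models())
    for chain in first:
        order = []
        for res in chain:
            hetflag, resseq, icode = res.get_id()
            if hetflag.strip():
                continue
            one = protein_letters_3to1.get(res.get_resname().upper())
            if one is None:
                continue
            pos = f"{resseq}{icode.strip()}"
            coords = np.array(
                [a.coord for a in res.get_atoms() if a.element != "H"], dtype=float
            )
            from .features import _ResidueData

            model.residues[(chain.id, pos)] = _ResidueData(one, coords)
            order.append(pos)
        if order:
            model.chain_order[chain.id] = order
    return model


# ---------------------------------------------------------------------------
# Profiles and matrices
# ---------------------------------------------------------------------------


def generate_profile(
    sequence: str, conservation_level: float, seed: int = 0
) -> ConservationProfile:
    """Single-sequence conservation profile at a fixed conservation level.

    At every position the native residue gets frequency
    ``conservation_level`` and the remaining mass is spread evenly over the
    other 19 amino acids; frequencies sum to one per position.
    """
    if not 0.0 < conservation_level <= 1.0:
        raise ValueError("conservation_level must be in (0, 1]")
    rows = []
    other = (1.0 - conservation_level) / 19.0
    for i, aa in enumerate(sequence):
        row = {a: other for a in AMINO_ACIDS}
        row[aa] = conservation_level
        row["position"] = str(i + 1)
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("position")
    return ConservationProfile(freqs=frame)


def generate_test_matrices(
    seed: int = 0,
) -> tuple[substitution_matrices.Array, PairPotential, PairPotential]:
    """Random symmetric matrices: a substitution matrix and two pair potentials.

    The substitution matrix is integer-valued in the BLOSUM range; the
    potentials are real-valued with unit spread.  All three are symmetric by
    construction and round-trip through their file formats.
    """
    rng = np.random.default_rng(seed)
    n = len(AMINO_ACIDS)

    ints = rng.integers(-4, 12, size=(n, n))
    sym_ints = np.triu(ints) + np.triu(ints, 1).T
    sub = substitution_matrices.Array(alphabet=AMINO_ACIDS, dims=2)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            sub[a, b] = float(sym_ints[i, j])

    def _potential(role: str) -> PairPotential:
        raw = rng.normal(size=(n, n))
        sym = (raw + raw.T) / 2.0
        frame = pd.DataFrame(sym, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))
        return PairPotential(values=frame, role=role)  # type: ignore[arg-type]

    return sub, _potential("sequence"), _potential("structural")


def write_substitution_matrix(matrix: substitution_matrices.Array, path: str | Path) -> None:
    """Write a substitution matrix in the standard NCBI text format."""
    Path(path).write_text(str(matrix))


# ---------------------------------------------------------------------------
# Complete miniature study
# ---------------------------------------------------------------------------


def make_fixture_study(
    out_dir: str | Path,
    n_variants_per_protein: int = 6,
    sequence_length: int = 12,
    n_proteins: int = 3,
    conservation_level: float = 0.7,
    seed: int = 0,
    break_structure: bool = False,
) -> dict[str, Path]:
    """Write a complete miniature study directory consumable by the pipeline.

    Emits toy PDB structures, conservation profiles, a substitution matrix,
    the two pair potentials and a variant table whose wild-type residues
    match the structures.  With ``break_structure`` the last protein's PDB
    is omitted, exercising the structural-exclusion path.  Returns the paths
    written, keyed by role.
    """
    out_dir = Path(out_dir)
    (out_dir / "structures").mkdir(parents=True, exist_ok=True)
    (out_dir / "profiles").mkdir(exist_ok=True)
    (out_dir / "matrices").mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)
    aas = np.array(list(AMINO_ACIDS))

    sub, sk, bv = generate_test_matrices(seed)
    paths = {
        "blosum": out_dir / "matrices" / "substitution.mat",
        "skolnick": out_dir / "matrices" / "skolnick.tsv",
        "bv": out_dir / "matrices" / "bv.tsv",
        "variants": out_dir / "variants.tsv",
    }
    write_substitution_matrix(sub, paths["blosum"])
    sk.write_tsv(paths["skolnick"])
    bv.write_tsv(paths["bv"])

    records = []
    for p in range(n_proteins):
        pid = f"T{p:03d}"
        seq = "".join(rng.choice(aas, size=sequence_length))
        spec = ToyStructureSpec(sequence=seq, mode="extended", name=pid)
        _, pdb_text = generate_toy_structure(spec)
        broken = break_structure and p == n_proteins - 1
        if not broken:
            (out_dir / "structures" / f"{pid}.pdb").write_text(pdb_text)
        # per-position conservation levels around the requested one, so the
        # conservation log-ratio varies across variants
        rows = []
        for i, aa in enumerate(seq):
            level = float(np.clip(conservation_level + rng.uniform(-0.25, 0.25), 0.06, 1.0))
            prof_row = {a: (1.0 - level) / 19.0 for a in AMINO_ACIDS}
            prof_row[aa] = level
            prof_row["position"] = str(i + 1)
            rows.append(prof_row)
        frame = pd.DataFrame(rows).set_index("position")
        ConservationProfile(freqs=frame).write_tsv(out_dir / "profiles" / f"{pid}.tsv")
        for _ in range(n_variants_per_protein):
            pos = int(rng.integers(1, sequence_length + 1))
            wt = seq[pos - 1]
            mut = str(rng.choice([a for a in AMINO_ACIDS if a != wt]))
            ddg = float(rng.normal(-0.5, 1.2))
            records.append(
                VariantRecord("fixture", pid, "A", str(pos), wt, mut, ddg)
            )
    # drop duplicate keys from random draws
    seen, unique = set(), []
    for r in records:
        if r.key not in seen:
            seen.add(r.key)
            unique.append(r)
    from .dataset_io import write_variant_table

    write_variant_table(Dataset("fixture", unique), paths["variants"])
    paths["structures"] = out_dir / "structures"
    paths["profiles"] = out_dir / "profiles"
    return paths
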