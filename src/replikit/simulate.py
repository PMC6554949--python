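"""Seeded synthetic-data generators for every analysis stage.

These generators produce inputs with exactly the statistical structure the
downstream analyses assume, so the whole pipeline can be exercised and
validated without any external data:

* :func:`simulate_paired_alignment` — species-matched orthologue families
  with independently drawn background columns and a set of *planted*
  covarying inter-family column pairs, the positive controls the coupling
  analysis must recover;
* :func:`simulate_titration` — noisy titration series drawn from the
  ligand-depletion binding isotherm at known (U, B, Kd);
* :func:`simulate_ct_table` — replicated qPCR Ct tables with known true
  fold changes against a reference target.

All generators are pure functions of their spec (including its seed): the
same spec yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from replikit.binding import TitrationSeries, binding_response, serial_dilution, DEFAULT_C_T
from replikit.msa import ALPHABET, GAP, AlignedFamily, FamilyRow


# ---------------------------------------------------------------------------
# paired alignments with planted couplings


@dataclass
class PlantedPair:
    """A covarying inter-family column pair.

    ``col_a``/``col_b`` are 1-based columns within family A / family B.
    States are drawn from the joint distribution P(a, b) proportional to
    exp(beta * [a == b]) over the sub-alphabet: ``beta = 0`` is
    independence, large ``beta`` approaches perfect state copying.  An
    explicit normalized ``joint`` table overrides ``beta``.
    """

    col_a: int
    col_b: int
    beta: float = 3.0
    joint: np.ndarray | None = None

    def joint_distribution(self, q_sub: int) -> np.ndarray:
        if self.joint is not None:
            J = np.asarray(self.joint, dtype=float)
            if J.shape != (q_sub, q_sub) or not np.isclose(J.sum(), 1.0):
                raise ValueError("explicit joint table must be (q_sub, q_sub) and sum to 1")
            return J
        J = np.exp(self.beta * np.eye(q_sub))
        return J / J.sum()


@dataclass
class CouplingSpec:
    """Recipe for a species-matched paired-alignment simulation.

    Defaults describe the standard validation scenario: 2000 species, two
    families of 30 columns each over a 4-letter sub-alphabet, and 5
    strongly coupled planted pairs.  ``redundancy = (n_copies, mut_rate)``
    appends near-duplicate copies of every species to exercise sequence
    reweighting; ``gap_rate`` converts non-reference positions to gaps.
    """

    n_species: int = 2000
    L_A: int = 30
    L_B: int = 30
    q_sub: int = 4
    n_planted: int = 5
    planted_pairs: list[PlantedPair] | None = None
    beta: float = 3.0
    redundancy: tuple[int, float] | None = None
    gap_rate: float = 0.0
    seed: int = 0

    def resolve_planted(self, rng: np.random.Generator) -> list[PlantedPair]:
        if self.planted_pairs is not None:
            pairs = self.planted_pairs
        else:
            cols_a = rng.choice(self.L_A, size=self.n_planted, replace=False) + 1
            cols_b = rng.choice(self.L_B, size=self.n_planted, replace=False) + 1
            pairs = [
                PlantedPair(int(a), int(b), beta=self.beta)
                for a, b in zip(cols_a, cols_b)
            ]
        seen_a = [p.col_a for p in pairs]
        seen_b = [p.col_b for p in pairs]
        if len(set(seen_a)) != len(pairs) or len(set(seen_b)) != len(pairs):
            raise ValueError("planted pairs overlap in a column")
        for p in pairs:
            if not (1 <= p.col_a <= self.L_A and 1 <= p.col_b <= self.L_B):
                raise ValueError(f"planted pair ({p.col_a}, {p.col_b}) out of range")
        return pairs


def simulate_paired_alignment(spec: CouplingSpec) -> tuple[AlignedFamily, AlignedFamily]:
    """Generate two species-matched aligned families with planted couplings.

    Background columns are i.i.d. uniform over the first ``q_sub`` letters
    of the amino-acid alphabet; planted column pairs are drawn jointly.
    The first species is the designated ungapped reference in both
    families.  Deterministic given the spec.
    """
    rng = np.random.default_rng(spec.seed)
    planted = spec.resolve_planted(rng)
    n, q = spec.n_species, spec.q_sub
    letters = np.array(list(ALPHABET[:q]))

    A = rng.integers(0, q, size=(n, spec.L_A))
    B = rng.integers(0, q, size=(n, spec.L_B))
    for p in planted:
        J = p.joint_distribution(q)
        flat = rng.choice(q * q, size=n, p=J.ravel())
        A[:, p.col_a - 1] = flat // q
        B[:, p.col_b - 1] = flat % q

    chars_a = letters[A]
    chars_b = letters[B]
    if spec.gap_rate > 0:
        # the reference (row 0) stays ungapped
        for chars in (chars_a, chars_b):
            mask = rng.random(chars.shape) < spec.gap_rate
            mask[0, :] = False
            chars[mask] = GAP

    species = [f"sp{k:04d}" for k in range(n)]
    rows_a = [
        FamilyRow(sp, f"{sp}|famA", "".join(row)) for sp, row in zip(species, chars_a)
    ]
    rows_b = [
        FamilyRow(sp, f"{sp}|famB", "".join(row)) for sp, row in zip(species, chars_b)
    ]

    if spec.redundancy is not None:
        n_copies, mut_rate = spec.redundancy
        for rows, L in ((rows_a, spec.L_A), (rows_b, spec.L_B)):
            originals = list(rows)
            for c in range(n_copies):
                for r in originals:
                    seq = np.array(list(r.residues))
                    mut = rng.random(L) < mut_rate
                    seq[mut] = letters[rng.integers(0, q, size=int(mut.sum()))]
                    rows.append(
                        FamilyRow(
                            f"{r.species_id}c{c}",
                            f"{r.species_id}c{c}|{r.seq_id.split('|')[1]}",
                            "".join(seq),
                        )
                    )

    fam_a = AlignedFamily(name="familyA", rows=rows_a, reference_seq_id=rows_a[0].seq_id)
    fam_b = AlignedFamily(name="familyB", rows=rows_b, reference_seq_id=rows_b[0].seq_id)
    return fam_a, fam_b


# ---------------------------------------------------------------------------
# MST titrations


@dataclass
class MstSimSpec:
    """Recipe for synthetic MST titrations.

    Defaults follow the standard assay layout: 16 two-fold serial dilutions
    of the ligand against a labelled target held at 20 nM, with additive
    Gaussian response noise.  Concentrations are molar.
    """

    U: float = 0.0
    B: float = 1.0
    Kd: float = 1.26e-6
    c_t: float = DEFAULT_C_T
    top: float = 12.8e-6
    n_dilutions: int = 16
    factor: float = 2.0
    noise_sd: float = 0.02
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Kd < 0 or self.c_t <= 0 or self.top <= 0 or self.noise_sd < 0:
            raise ValueError("MstSimSpec requires positive concentrations and noise_sd >= 0")


def simulate_titration(spec: MstSimSpec) -> list[TitrationSeries]:
    """Draw replicate titration series from the binding isotherm."""
    rng = np.random.default_rng(spec.seed)
    C = serial_dilution(spec.top, spec.n_dilutions, spec.factor)
    clean = binding_response(C, spec.U, spec.B, spec.c_t, spec.Kd)
    out = []
    for r in range(spec.n_replicates):
        noise = rng.normal(0.0, spec.noise_sd, size=len(C)) if spec.noise_sd else 0.0
        out.append(
            TitrationSeries(
                concentrations=C,
                responses=clean + noise,
                c_t=spec.c_t,
                label=f"rep{r}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# qPCR Ct tables


@dataclass
class CtSimSpec:
    """Recipe for a synthetic qPCR Ct table.

    ``true_ratios`` maps genotype -> target -> fold change relative to the
    control genotype; the control's ratios are 1.  A target's Ct is shifted
    by -log2(ratio) cycles from ``base_ct`` (fewer template copies mean
    more cycles), the reference target sits at ``base_ct``, and independent
    Gaussian noise of ``noise_sd`` cycles is added per well.
    """

    true_ratios: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"mutant": {"mito": 0.7}}
    )
    control_genotype: str = "WT"
    reference_target: str = "nuclear_ref"
    base_ct: float = 22.0
    noise_sd: float = 0.2
    n_replicates: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for genotype, targets in self.true_ratios.items():
            for target, ratio in targets.items():
                if ratio <= 0:
                    raise ValueError(f"true ratio for {genotype}/{target} must be > 0")


def simulate_ct_table(spec: CtSimSpec) -> pd.DataFrame:
    """Generate a replicated Ct table with known fold changes."""
    rng = np.random.default_rng(spec.seed)
    targets = sorted({t for m in spec.true_ratios.values() for t in m})
    genotypes = [spec.control_genotype] + [
        g for g in spec.true_ratios if g != spec.control_genotype
    ]
    records = []
    for genotype in genotypes:
        ratios = spec.true_ratios.get(genotype, {})
        for rep in range(1, spec.n_replicates + 1):
            for target in targets + [spec.reference_target]:
                if target == spec.reference_target:
                    mean_ct = spec.base_ct
                else:
                    ratio = 1.0 if genotype == spec.control_genotype else ratios.get(target, 1.0)
                    mean_ct = spec.base_ct - np.log2(ratio)
                noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 0.0
                records.append(
                    {
                        "genotype": genotype,
                        "target": target,
                        "replicate": rep,
                        "ct": mean_ct + noise,
                    }
                )
    return pd.DataFrame(records)
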