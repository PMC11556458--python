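"""Synthetic mother/child hair-proteome cohorts.

The study data are not public, so every downstream stage is exercised on
simulated cohorts that reproduce the statistical structure the analysis
assumes:

* 8 families of one mother plus two biological children, and 16
  unrelated children (40 subjects), ~2,269 proteins of which a fraction
  are structural (keratin/KAP-like);
* deeper sampling in mothers (higher total spectral counts);
* familial sharing of presence/absence profiles — a child is more likely
  to express a protein her mother expresses;
* a subset of proteins whose abundance scales with age, and a subset
  elevated in one sex.

Counts follow a two-part model: presence is Bernoulli per protein per
subject, and conditional on presence the count is 1 plus a gamma-mixed
Poisson (negative binomial) draw, so presence always implies a non-zero
count.  The two parts are decoupled on purpose: the family permutation
test operates on Boolean presence profiles while every other stage uses
counts, and a single count distribution could not plant the familial
effect without also moving abundances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .data import SpectralCountMatrix, SubjectMetadata

__all__ = ["CohortSpec", "generate_cohort", "truth_table"]


@dataclass
class CohortSpec:
    """Parameters of the simulated cohort.

    Defaults mirror the enrolled study design (8 families x [mother + 2
    children] + 16 unrelated children = 40 subjects; 2,269 proteins) and
    a moderate, plausible effect structure everywhere the design leaves
    a free choice.

    Attributes
    ----------
    mother_depth_multiplier
        Multiplies mothers' expected counts; >1 reproduces the deeper
        maternal proteome (more PSMs and more proteins observed).
    family_share_boost
        Added to a related child's presence probability for each protein
        the mother expresses; 0 removes the familial effect entirely
        (the null of the family permutation test).
    baseline_log_abundance
        Optional per-protein natural-log mean of the positive count
        part; drawn Normal(log 6, 0.8) when omitted.
    dispersion
        Gamma-Poisson overdispersion; variance = mu + dispersion * mu^2.
    """

    n_families: int = 8
    children_per_family: int = 2
    n_unrelated_children: int = 16
    n_proteins: int = 2269
    structural_fraction: float = 0.1
    baseline_log_abundance: Optional[np.ndarray] = None
    dispersion: float = 0.7
    mother_depth_multiplier: float = 1.5
    family_share_boost: float = 0.3
    n_age_proteins: int = 100
    age_effect_size: float = 0.5
    n_sex_proteins: int = 30
    sex_effect_size: float = 1.5
    presence_prob: float = 0.5
    seed: Optional[int] = None

    def validate(self) -> None:
        if not (0 <= self.presence_prob <= 1):
            raise ValueError(f"presence_prob must be in [0,1], got {self.presence_prob}")
        if not (0 <= self.family_share_boost <= 1):
            raise ValueError(f"family_share_boost must be in [0,1], got {self.family_share_boost}")
        if not (0 <= self.structural_fraction <= 1):
            raise ValueError(f"structural_fraction must be in [0,1], got {self.structural_fraction}")
        for name in ("mother_depth_multiplier", "sex_effect_size", "dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("n_families", "children_per_family", "n_proteins"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_unrelated_children", "n_age_proteins", "n_sex_proteins"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        n_structural = int(np.floor(self.structural_fraction * self.n_proteins))
        if self.n_age_proteins + self.n_sex_proteins > self.n_proteins - n_structural:
            raise ValueError(
                "n_age_proteins + n_sex_proteins exceeds the number of "
                "non-structural proteins"
            )
        if self.baseline_log_abundance is not None and len(self.baseline_log_abundance) != self.n_proteins:
            raise ValueError("baseline_log_abundance length must equal n_proteins")

    @property
    def n_subjects(self) -> int:
        return self.n_families * (1 + self.children_per_family) + self.n_unrelated_children


def _protein_plan(spec: CohortSpec) -> pd.DataFrame:
    """Per-protein ground truth, drawn from a dedicated RNG stream.

    Uses stream 0 of the spec seed so that :func:`truth_table` and
    :func:`generate_cohort` agree without sharing state.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
    n = spec.n_proteins
    width = max(4, len(str(n)))
    protein_ids = np.array([f"PROT{i + 1:0{width}d}" for i in range(n)])

    n_structural = int(np.floor(spec.structural_fraction * n))
    order = rng.permutation(n)
    structural_idx = order[:n_structural]
    free = order[n_structural:]
    age_idx = free[: spec.n_age_proteins]
    sex_idx = free[spec.n_age_proteins : spec.n_age_proteins + spec.n_sex_proteins]

    structural = np.zeros(n, dtype=bool)
    structural[structural_idx] = True
    age_linked = np.zeros(n, dtype=bool)
    age_linked[age_idx] = True
    sex_linked = np.zeros(n, dtype=bool)
    sex_linked[sex_idx] = True

    if spec.baseline_log_abundance is not None:
        baseline = np.asarray(spec.baseline_log_abundance, dtype=float)
    else:
        baseline = rng.normal(np.log(6.0), 0.8, size=n)

    return pd.DataFrame(
        {
            "structural": structural,
            "age_linked": age_linked,
            "sex_linked": sex_linked,
            "family_shared": np.full(n, spec.family_share_boost > 0),
            "baseline_log_abundance": baseline,
        },
        index=pd.Index(protein_ids, name="protein_id"),
    )


def truth_table(spec: CohortSpec) -> pd.DataFrame:
    """Ground-truth per-protein labels for a given spec.

    Columns ``structural``, ``age_linked``, ``sex_linked`` and
    ``family_shared`` (the familial presence-sharing effect applies to
    every protein whenever ``family_share_boost > 0``).  Deterministic in
    ``spec.seed`` and consistent with :func:`generate_cohort`.
    """
    spec.validate()
    return _protein_plan(spec).drop(columns="baseline_log_abundance")


def _metadata_frame(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    fam_width = max(3, len(str(spec.n_families + spec.n_unrelated_children)))
    for f in range(spec.n_families):
        fam = f"SF{f + 1:0{fam_width}d}"
        mother_age = rng.uniform(33 * 12, 45 * 12)
        rows.append((f"{fam}_Mo", fam, "mother", mother_age, "F", True))
        for c in range(spec.children_per_family):
            age = rng.uniform(6, 72)
            sex = "F" if rng.random() < 0.5 else "M"
            rows.append((f"{fam}_C{c + 1}", fam, "child", age, sex, True))
    for u in range(spec.n_unrelated_children):
        fam = f"SU{u + 1:0{fam_width}d}"
        age = rng.uniform(6, 72)
        sex = "F" if rng.random() < 0.5 else "M"
        rows.append((f"{fam}_C1", fam, "child", age, sex, False))
    return pd.DataFrame(
        rows, columns=["subject_id", "family_id", "role", "age_months", "sex", "related"]
    )


def generate_cohort(spec: CohortSpec = CohortSpec()) -> tuple[SpectralCountMatrix, SubjectMetadata]:
    """Draw one synthetic cohort.

    Returns a validated count matrix (proteins x subjects) and matching
    metadata.  Mothers' ages fall in 33-45 years, children's in 0.5-6
    years.  Fully deterministic in ``spec.seed``.
    """
    spec.validate()
    plan = _protein_plan(spec)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1,)))

    meta_frame = _metadata_frame(spec, rng)
    n_prot, n_subj = spec.n_proteins, spec.n_subjects
    is_mother = (meta_frame["role"] == "mother").to_numpy()
    is_female = (meta_frame["sex"] == "F").to_numpy()
    ages = meta_frame["age_months"].to_numpy()
    z_age = (ages - ages.mean()) / ages.std()

    # presence: mothers and unrelated children at baseline; related children
    # boosted where their mother expresses the protein
    presence = np.zeros((n_prot, n_subj), dtype=bool)
    mother_cols = np.flatnonzero(is_mother)
    presence[:, mother_cols] = rng.random((n_prot, len(mother_cols))) < spec.presence_prob
    family_of = meta_frame["family_id"].to_numpy()
    mother_col_of_family = {family_of[c]: c for c in mother_cols}
    child_cols = np.flatnonzero(~is_mother)
    for c in child_cols:
        mc = mother_col_of_family.get(family_of[c])
        p = np.full(n_prot, spec.presence_prob)
        if mc is not None:
            p = np.clip(p + spec.family_share_boost * presence[:, mc], 0.0, 1.0)
        presence[:, c] = rng.random(n_prot) < p

    # conditional counts: 1 + gamma-mixed Poisson with subject-level multipliers
    mu = np.exp(plan["baseline_log_abundance"].to_numpy())[:, None] * np.ones((1, n_subj))
    mu[:, is_mother] *= spec.mother_depth_multiplier
    age_rows = plan["age_linked"].to_numpy()
    mu[age_rows, :] *= np.exp(spec.age_effect_size * z_age)[None, :]
    sex_rows = plan["sex_linked"].to_numpy()
    mu[np.ix_(sex_rows, is_female)] *= spec.sex_effect_size

    shape = 1.0 / spec.dispersion
    lam = rng.gamma(shape, mu * spec.dispersion)
    counts = presence * (1 + rng.poisson(lam))

    matrix = SpectralCountMatrix(
        pd.DataFrame(counts, index=plan.index, columns=meta_frame["subject_id"]),
        plan["structural"].copy(),
    )
    return matrix, SubjectMetadata(meta_frame)
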