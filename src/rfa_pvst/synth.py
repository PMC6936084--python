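"""Synthetic cohort generator.

Emulates the statistical structure of the post-splenectomy study cohort
so the whole pipeline is testable without the clinical data: two
unbalanced outcome classes (52 thrombosis vs 40 without), boolean therapy
indicators with strong class association, continuous lab indexes with
configurable standardized class mean-shifts, correlated redundant feature
blocks, and pure-noise fillers.  All randomness flows from a single seed
through a per-feature split of the seed sequence, so results do not
depend on generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .cohort import ClinicalCohort, CohortSchema, FeatureDef, RawPatientRecord, default_schema

__all__ = ["PlantedFeature", "RedundantCopy", "SyntheticSpec", "generate",
           "generate_longitudinal", "paper_like_spec", "single_signal_spec"]


@dataclass(frozen=True)
class PlantedFeature:
    """A feature carrying class signal.

    Continuous: unit-variance Gaussian, positive class mean shifted by
    ``effect`` (a standardized mean-shift delta).  Boolean: Bernoulli with
    class rates sigmoid(+effect/2) and sigmoid(-effect/2) (``effect`` is
    the log-odds separation).
    """

    feature_id: int
    kind: str  # "boolean" | "continuous"
    effect: float

    def __post_init__(self):
        if self.effect < 0:
            raise ValueError("effect size must be non-negative")
        if self.kind not in ("boolean", "continuous"):
            raise ValueError("kind must be 'boolean' or 'continuous'")


@dataclass(frozen=True)
class RedundantCopy:
    """A correlated copy: rho * standardized(source) + sqrt(1-rho^2) * noise."""

    feature_id: int
    source_id: int
    rho: float

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")


@dataclass
class SyntheticSpec:
    """Cohort recipe; defaults mirror the study scale (92 patients, 33
    indexes)."""

    n_pos: int = 52
    n_neg: int = 40
    n_features: int = 33
    planted: list = field(default_factory=list)
    redundant: list = field(default_factory=list)
    seed: int = 0
    rho_truth_threshold: float = 0.9  # copies at/above this count as ground truth

    def __post_init__(self):
        ids = [p.feature_id for p in self.planted] + [c.feature_id for c in self.redundant]
        if len(set(ids)) != len(ids):
            raise ValueError("planted/redundant feature ids overlap")
        if any(i < 1 or i > self.n_features for i in ids):
            raise ValueError("feature ids must lie in 1..n_features")
        sources = {p.feature_id for p in self.planted}
        for c in self.redundant:
            if c.source_id not in sources:
                raise ValueError(f"redundant copy {c.feature_id} has unknown source")


def paper_like_spec(seed: int = 0) -> SyntheticSpec:
    """Study-shaped preset: 52/40 patients, 33 features; two strongly
    class-associated boolean therapy indicators (ids 32, 33; log-odds 3),
    three moderate continuous lab signals (D-D 31, CHOL 7, Ca 17;
    delta = 0.5), five redundant copies at rho = 0.8, the rest pure
    noise."""
    return SyntheticSpec(
        planted=[
            PlantedFeature(32, "boolean", 3.0),
            PlantedFeature(33, "boolean", 3.0),
            PlantedFeature(31, "continuous", 0.5),
            PlantedFeature(7, "continuous", 0.5),
            PlantedFeature(17, "continuous", 0.5),
        ],
        redundant=[
            RedundantCopy(5, 31, 0.8),
            RedundantCopy(6, 7, 0.8),
            RedundantCopy(8, 17, 0.8),
            RedundantCopy(9, 31, 0.8),
            RedundantCopy(10, 7, 0.8),
        ],
        seed=seed,
    )


def single_signal_spec(delta: float = 3.0, seed: int = 0) -> SyntheticSpec:
    """Study-shaped preset with exactly one planted continuous feature of
    standardized shift delta (id 31) and 32 noise features."""
    return SyntheticSpec(planted=[PlantedFeature(31, "continuous", delta)], seed=seed)


def _schema_for(spec: SyntheticSpec) -> CohortSchema:
    # kind reflects what was actually generated: only planted booleans are 0/1
    boolean_ids = {p.feature_id for p in spec.planted if p.kind == "boolean"}
    if spec.n_features == 33:
        base = default_schema()
        return CohortSchema([
            FeatureDef(f.id, f.name,
                       "boolean" if f.id in boolean_ids else "continuous", f.static)
            for f in base
        ])
    return CohortSchema([
        FeatureDef(j, f"X{j}", "boolean" if j in boolean_ids else "continuous")
        for j in range(1, spec.n_features + 1)
    ])


def generate(spec: SyntheticSpec) -> tuple[ClinicalCohort, dict]:
    """Draw one cohort and its ground truth.

    Returns (cohort, truth); truth lists the planted ids, the strong
    planted ids (boolean indicators or continuous shifts >= 2), redundant
    copies above the declared rho threshold, and the full recipe.
    """
    m = spec.n_pos + spec.n_neg
    labels = np.concatenate([np.ones(spec.n_pos, int), -np.ones(spec.n_neg, int)])
    pos = labels == 1
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_features)
    rngs = {j + 1: np.random.default_rng(children[j]) for j in range(spec.n_features)}
    values = np.empty((m, spec.n_features))
    planted_by_id = {p.feature_id: p for p in spec.planted}
    copies_by_id = {c.feature_id: c for c in spec.redundant}
    # planted and noise features first (copies need their source draws)
    for j in range(1, spec.n_features + 1):
        if j in copies_by_id:
            continue
        rng = rngs[j]
        p = planted_by_id.get(j)
        if p is None:
            values[:, j - 1] = rng.standard_normal(m)
        elif p.kind == "continuous":
            values[:, j - 1] = rng.standard_normal(m) + p.effect * pos
        else:
            rate = np.where(pos, expit(p.effect / 2.0), expit(-p.effect / 2.0))
            values[:, j - 1] = (rng.random(m) < rate).astype(float)
    for c in spec.redundant:
        rng = rngs[c.feature_id]
        src = values[:, c.source_id - 1]
        sd = src.std()
        z = (src - src.mean()) / (sd if sd > 0 else 1.0)
        values[:, c.feature_id - 1] = c.rho * z + np.sqrt(1 - c.rho**2) * rng.standard_normal(m)
    schema = _schema_for(spec)
    cohort = ClinicalCohort(values, labels, schema)
    strong = sorted(
        p.feature_id for p in spec.planted
        if p.kind == "boolean" or p.effect >= 2.0
    )
    truth = {
        "planted": sorted(planted_by_id),
        "strong": strong,
        "redundant_truth": sorted(
            c.feature_id for c in spec.redundant if c.rho >= spec.rho_truth_threshold
        ),
        "spec": {
            "n_pos": spec.n_pos, "n_neg": spec.n_neg, "n_features": spec.n_features,
            "seed": spec.seed,
            "planted": [(p.feature_id, p.kind, p.effect) for p in spec.planted],
            "redundant": [(c.feature_id, c.source_id, c.rho) for c in spec.redundant],
        },
    }
    return cohort, truth


def generate_longitudinal(
    spec: SyntheticSpec, visits_per_patient: int = 5, visit_noise: float = 0.1
) -> tuple[list[RawPatientRecord], dict]:
    """Expand a cohort into raw per-visit records.

    Measurable indexes emit ``visits_per_patient`` dated values built from
    antisymmetric noise pairs around the latent cohort value (plus an
    exact middle visit when the count is odd), so the per-patient median
    recovers the latent value exactly for odd visit counts and within
    ``visit_noise`` always.  Static indexes go to ``static_values``.
    """
    if visits_per_patient < 1:
        raise ValueError("visits_per_patient must be >= 1")
    cohort, truth = generate(spec)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 2**16 + 1)))
    base = np.datetime64("2019-01-02")
    records = []
    for i in range(cohort.m):
        rec = RawPatientRecord(patient_id=f"P{i:04d}", label=int(cohort.labels[i]))
        for j, f in enumerate(cohort.schema):
            v = cohort.values[i, j]
            if f.static:
                rec.static_values[f.name] = int(v) if f.kind == "boolean" else float(v)
                continue
            half = visits_per_patient // 2
            deltas = rng.uniform(0, visit_noise, size=half)
            offsets = np.concatenate([deltas, -deltas, [0.0]] if visits_per_patient % 2
                                     else [deltas, -deltas])
            rng.shuffle(offsets)
            for t, off in enumerate(offsets):
                date = str(base + np.timedelta64(t, "D"))
                rec.measurements.append((f.name, date, float(v + off)))
        records.append(rec)
    return records, truth
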