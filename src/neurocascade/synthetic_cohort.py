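"""Seeded synthetic cohort generator and data splitters.

The generator emulates the statistical structure of an elderly
dementia-screening cohort: a strong (~9:1) control:case imbalance, four
demographic variables (age, sex, education, depression score), an MMSE total
score, and ~92 bounded integer neuropsychological battery sub-scores arranged
in correlated instrument blocks whose means shift with diagnosis.  Sub-scores
are drawn from a Gaussian copula with block-diagonal equicorrelation and then
mapped to bounded count-like ranges by rounding and clipping.

Missingness is sparse and concentrated on two designated "hotspot" variables
(emulating clock-drawing scores, which real cohorts most often lack), with
one or two missing cells per affected subject being most common.  The
mechanism defaults to MCAR; a configurable label tilt produces MAR
missingness where cases are likelier to be affected.

All label-dependent mean shifts scale linearly with ``effect_size``, so
``effect_size=0`` yields an exact null cohort in which no variable separates
the classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from neurocascade.dataset import (
    ROLE_BATTERY,
    ROLE_DEMOGRAPHIC,
    ROLE_MMSE,
    CohortDataset,
)

DEMOGRAPHIC_NAMES = ("age", "sex_female", "education_years", "depression_score")

# per-affected-subject missing-cell count distribution: mode at 1-2 cells
_MISS_COUNTS = np.array([1, 2, 3, 4])
_MISS_PROBS = np.array([0.55, 0.30, 0.10, 0.05])
_HOTSPOT_FIRST_P = 0.85  # first missing cell lands on a hotspot variable
_HOTSPOT_EXTRA_P = 0.50


@dataclass
class CohortConfig:
    """Generation parameters; defaults emulate the study cohort scale."""

    n_subjects: int = 3101
    positive_fraction: float = 435 / 3101
    n_domains: int = 23
    vars_per_domain: int = 4
    n_informative: int = 40
    effect_size: float = 1.0
    within_domain_corr: float = 0.6
    missing_subject_fraction: float = 75 / 3101
    missing_hotspot_vars: tuple[str, ...] = ("clox_s1", "clox_s2")
    mar_label_shift: float = 0.0
    seed: int = 0
    # label-shift multipliers for the screener-side variables, in effect_size
    # units; the MMSE separation in dementia cohorts is large (controls ~27+-2,
    # cases typically below 20), hence the 2.5-SD default
    mmse_shift: float = 2.5
    demographic_shifts: dict = field(
        default_factory=lambda: {
            "age": 0.95,
            "sex_female": 0.33,
            "education_years": -0.42,
            "depression_score": 0.6,
        }
    )

    def __post_init__(self) -> None:
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")
        if not 0 <= self.within_domain_corr < 1:
            raise ValueError("within_domain_corr must be in [0, 1)")
        if self.n_informative > self.n_domains * self.vars_per_domain:
            raise ValueError("n_informative exceeds number of battery variables")
        if min(self.n_subjects, self.n_domains, self.vars_per_domain) < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.missing_subject_fraction < 1:
            raise ValueError("missing_subject_fraction must be in [0, 1)")

    @property
    def n_battery(self) -> int:
        return self.n_domains * self.vars_per_domain

    def battery_names(self) -> list[str]:
        """Instrument-block variable names; the last block is the clock-drawing
        style instrument carrying the missingness hotspots."""
        names = []
        for d in range(self.n_domains):
            stem = "clox" if d == self.n_domains - 1 else f"dom{d + 1:02d}"
            names += [f"{stem}_s{j + 1}" for j in range(self.vars_per_domain)]
        return names


def _bounded_score(latent: np.ndarray, center: float, scale: float, lo: float, hi: float) -> np.ndarray:
    return np.clip(np.round(center + scale * latent), lo, hi)


def generate_cohort(config: CohortConfig) -> CohortDataset:
    """Draw a complete (no missing cells) cohort from the configured model.

    Deterministic for a fixed config: the same seed reproduces the dataset
    bit for bit.  Class counts follow ``positive_fraction`` exactly up to
    rounding.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    es = config.effect_size

    n_pos = int(round(n * config.positive_fraction))
    n_pos = min(max(n_pos, 1), n - 1)
    labels = np.zeros(n, dtype=np.int64)
    labels[rng.permutation(n)[:n_pos]] = 1

    # battery sub-scores: equicorrelated Gaussian blocks per instrument
    rho = config.within_domain_corr
    m_b = config.n_battery
    latent = np.empty((n, m_b))
    for d in range(config.n_domains):
        shared = rng.standard_normal((n, 1))
        eps = rng.standard_normal((n, config.vars_per_domain))
        block = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps
        latent[:, d * config.vars_per_domain : (d + 1) * config.vars_per_domain] = block

    # informative variables: evenly spread over the battery; cases score lower
    if config.n_informative > 0:
        info_idx = np.unique(
            np.round(np.linspace(0, m_b - 1, config.n_informative)).astype(int)
        )
        latent[:, info_idx] -= es * labels[:, None]
    battery = _bounded_score(latent, center=8.0, scale=2.4, lo=0, hi=15)

    # MMSE total (0-30): cases shifted down by mmse_shift * effect_size SDs
    z = rng.standard_normal(n) - config.mmse_shift * es * labels
    mmse = _bounded_score(z, center=27.0, scale=2.0, lo=0, hi=30)

    # demographics, marginals loosely matching an elderly Korean cohort
    shifts = config.demographic_shifts
    age = 69.5 + 6.5 * (rng.standard_normal(n) + shifts["age"] * es * labels)
    age = np.clip(np.round(age), 60, 100)
    p_female = 1.0 / (1.0 + np.exp(-(0.12 + shifts["sex_female"] * es * labels)))
    sex = (rng.random(n) < p_female).astype(float)
    edu = 9.6 + 5.3 * (rng.standard_normal(n) + shifts["education_years"] * es * labels)
    edu = np.clip(np.round(edu), 0, 22)
    dep = 8.0 + 5.0 * (rng.standard_normal(n) + shifts["depression_score"] * es * labels)
    dep = np.clip(np.round(dep), 0, 30)

    values = np.column_stack([age, sex, edu, dep, mmse, battery])
    names = list(DEMOGRAPHIC_NAMES) + ["mmse_total"] + config.battery_names()
    roles = (
        [ROLE_DEMOGRAPHIC] * 4 + [ROLE_MMSE] + [ROLE_BATTERY] * m_b
    )
    return CohortDataset(
        values=values,
        labels=labels,
        variable_names=names,
        variable_roles=roles,
        meta={"generator": "synthetic_cohort", "config": _jsonable(asdict(config))},
    )


def _jsonable(d: dict) -> dict:
    return {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in d.items()
    }


def inject_missingness(dataset: CohortDataset, config: CohortConfig) -> CohortDataset:
    """Blank battery cells of a complete cohort per the missingness model.

    A ``missing_subject_fraction`` share of subjects loses at least one cell;
    hotspot variables receive most of the blanks; the per-subject missing
    count has its mode at 1-2 cells.  The label and the MMSE total score are
    never blanked, so the stage-1 screener is always computable.
    """
    if not dataset.is_complete:
        raise ValueError("inject_missingness requires a complete dataset")
    hotspot_idx = [dataset.var_index(v) for v in config.missing_hotspot_vars]
    for i in hotspot_idx:
        if dataset.variable_roles[i] != ROLE_BATTERY:
            raise ValueError("hotspot variables must be battery sub-scores")
    n_affected = int(round(dataset.n_subjects * config.missing_subject_fraction))
    if n_affected == 0:
        return dataset.with_values(dataset.values)

    rng = np.random.default_rng(config.seed + 1_000_003)
    weights = 1.0 + config.mar_label_shift * dataset.labels
    weights = weights / weights.sum()
    affected = rng.choice(dataset.n_subjects, size=n_affected, replace=False, p=weights)

    battery_idx = dataset.columns_with_role(ROLE_BATTERY)
    values = dataset.values.copy()
    for row in affected:
        n_miss = rng.choice(_MISS_COUNTS, p=_MISS_PROBS)
        chosen: set[int] = set()
        for j in range(n_miss):
            p_hot = _HOTSPOT_FIRST_P if j == 0 else _HOTSPOT_EXTRA_P
            pool = hotspot_idx if rng.random() < p_hot else battery_idx
            avail = [c for c in pool if c not in chosen]
            if not avail:
                avail = [c for c in battery_idx if c not in chosen]
            if not avail:
                break
            chosen.add(int(rng.choice(avail)))
        for col in chosen:
            values[row, col] = np.nan
    return dataset.with_values(values)


def split_train_test(
    dataset: CohortDataset, test_fraction: float, seed: int
) -> tuple[CohortDataset, CohortDataset]:
    """Label-stratified disjoint train/test partition, deterministic per seed."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    idx = np.arange(dataset.n_subjects)
    n_test = int(round(dataset.n_subjects * test_fraction))
    if not 0 < n_test < dataset.n_subjects:
        raise ValueError("test_fraction leaves an empty partition")
    train_idx, test_idx = train_test_split(
        idx,
        test_size=n_test,
        stratify=dataset.labels,
        random_state=seed,
    )
    train = dataset.take_rows(np.sort(train_idx))
    test = dataset.take_rows(np.sort(test_idx))
    for part in (train, test):
        if part.labels.sum() == 0 or part.labels.sum() == part.n_subjects:
            raise ValueError("split left one part without both classes")
    return train, test


def kfold_split(
    dataset: CohortDataset, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold indices; every subject lands in exactly one
    validation fold."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > dataset.n_subjects:
        raise ValueError("k exceeds number of subjects")
    n_pos = int(dataset.labels.sum())
    if k > n_pos or k > dataset.n_subjects - n_pos:
        raise ValueError("k exceeds the size of the minority class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (train_idx, val_idx)
        for train_idx, val_idx in skf.split(dataset.values, dataset.labels)
    ]
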