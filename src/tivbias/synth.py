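"""Synthetic multi-site GMV-like cohorts with a controllable TIV confound.

The generator emulates the statistical structure that a voxel-based
grey-matter-volume (GMV) study presents to a sex classifier:

* per-sex total-intracranial-volume (TIV) distributions that overlap but are
  clearly separated (men larger on average);
* a global multiplicative coupling of every feature to TIV of which a fraction
  ``scaling_leak`` survives imperfect TIV correction — i.e. the confound
  pathway;
* an additive sex-typed spatial pattern, constructed *orthogonal* to the
  TIV-scaling direction, so that "signal beyond brain size" is a controllable
  ground truth;
* linear age-related GMV decline, additive site offsets and iid noise.

Application samples add transgender groups (TM: assigned female, identifies
male; TW: assigned male, identifies female) whose TIV either matches their
sex assigned at birth or falls midway between the sex means, and whose
feature pattern can be mixed between sex and gender identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CohortConfig, TransScenario

__all__ = ["FeatureMatrix", "generate_cohort", "generate_application_sample"]

SUBJECT_COLUMNS = ["id", "site", "sex", "gender_group", "age", "tiv", "total_gmv"]

_APP_SITE = "siteApp"


@dataclass
class FeatureMatrix:
    """Subjects x features matrix with row-aligned subject ids."""

    ids: list[str]
    values: np.ndarray  # (n_subjects, n_features), float64

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.ids):
            raise ValueError("values must be 2-D with one row per id")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def loc(self, ids) -> np.ndarray:
        """Rows for the given ids, in the given order."""
        index = {s: i for i, s in enumerate(self.ids)}
        try:
            rows = [index[s] for s in ids]
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"id {e.args[0]!r} not in feature matrix") from None
        return self.values[rows]


@dataclass
class _Structure:
    """Fixed per-universe quantities shared by all subjects of one seed."""

    base: np.ndarray          # per-feature baseline GMV (positive)
    scaling_dir: np.ndarray   # unit vector along `base`: the TIV direction
    pattern: np.ndarray       # unit sex-typed pattern, orthogonal to scaling_dir
    decline: np.ndarray       # per-feature age-decline loading
    site_offsets: np.ndarray  # (n_sites + 1, n_features); last row = app site
    site_names: list[str]


def _build_structure(config: CohortConfig) -> _Structure:
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    p = config.n_features
    base = rng.uniform(1.0, 3.0, size=p)
    scaling_dir = base / np.linalg.norm(base)

    k = max(1, int(round(config.signal_sparsity * p)))
    pattern = np.zeros(p)
    support = rng.choice(p, size=k, replace=False)
    pattern[support] = rng.choice([-1.0, 1.0], size=k)
    # Gram-Schmidt against the scaling direction, then renormalise
    pattern -= (pattern @ scaling_dir) * scaling_dir
    norm = np.linalg.norm(pattern)
    if norm < 1e-12:  # pragma: no cover - measure-zero draw
        raise RuntimeError("degenerate pattern draw; change seed or sparsity")
    pattern /= norm

    decline = rng.uniform(0.5, 1.5, size=p)
    site_offsets = rng.normal(0.0, config.site_offset_sd, size=(config.n_sites + 1, p))
    site_names = [f"site{j:02d}" for j in range(config.n_sites)] + [_APP_SITE]
    return _Structure(base, scaling_dir, pattern, decline, site_offsets, site_names)


def synthesize_features(
    structure: _Structure,
    config: CohortConfig,
    tiv: np.ndarray,
    age: np.ndarray,
    pattern_sign: np.ndarray,
    site_index: np.ndarray,
    noise: np.ndarray,
    pool_mean_tiv: float | None = None,
    mean_age: float | None = None,
) -> np.ndarray:
    """Deterministic feature synthesis given all stochastic draws.

    feature_i(s) = base_i * (1 + leak * (tiv_s - pool_mean) / pool_mean)
                 + amplitude * pattern_i * sign_s
                 + age_slope * (age_s - mean_age) * decline_i
                 + site_offset + noise

    Exposed separately from :func:`generate_cohort` so that properties such as
    monotonicity of row sums in TIV can be checked with every other draw held
    fixed.
    """
    tiv = np.asarray(tiv, float)
    pool_mean = float(np.mean(tiv)) if pool_mean_tiv is None else float(pool_mean_tiv)
    mean_a = float(np.mean(age)) if mean_age is None else float(mean_age)
    rel = config.scaling_leak * (tiv - pool_mean) / pool_mean
    X = (
        structure.base[None, :] * (1.0 + rel[:, None])
        + config.signal_amplitude * np.outer(pattern_sign, structure.pattern)
        + config.age_slope * np.outer(np.asarray(age, float) - mean_a, structure.decline)
        + structure.site_offsets[np.asarray(site_index, int)]
        + noise
    )
    return X


def _assemble(ids, sites, sex, gender_group, age, tiv, X) -> tuple[pd.DataFrame, FeatureMatrix]:
    subjects = pd.DataFrame(
        {
            "id": ids,
            "site": sites,
            "sex": sex,
            "gender_group": gender_group,
            "age": np.round(age, 3),
            "tiv": np.round(tiv, 3),
            "total_gmv": X.sum(axis=1),
        }
    )
    return subjects, FeatureMatrix(ids=list(ids), values=X)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, FeatureMatrix]:
    """Draw a cisgender training pool of ``2 * n_per_sex`` subjects.

    Returns a subject table (columns ``id site sex gender_group age tiv
    total_gmv``) and the aligned :class:`FeatureMatrix`.  Fully deterministic
    given ``config.seed``.
    """
    structure = _build_structure(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    n = config.n_per_sex

    sex = np.array(["F"] * n + ["M"] * n)
    gender_group = np.where(sex == "F", "CW", "CM")
    tiv = np.concatenate(
        [
            rng.normal(config.tiv_mean_female, config.tiv_sd, size=n),
            rng.normal(config.tiv_mean_male, config.tiv_sd, size=n),
        ]
    )
    tiv = np.clip(tiv, 1.0, None)  # tiv > 0 invariant
    age = rng.uniform(config.age_range[0], config.age_range[1], size=2 * n)
    site_index = rng.integers(0, config.n_sites, size=2 * n)
    pattern_sign = np.where(sex == "M", 1.0, -1.0)
    noise = rng.normal(0.0, config.noise_sd, size=(2 * n, config.n_features))

    X = synthesize_features(structure, config, tiv, age, pattern_sign, site_index, noise)
    ids = [f"C{i:05d}" for i in range(2 * n)]
    sites = [structure.site_names[j] for j in site_index]
    return _assemble(ids, sites, sex, gender_group, age, tiv, X)


def generate_application_sample(
    config: CohortConfig, scenario: TransScenario
) -> tuple[pd.DataFrame, FeatureMatrix]:
    """Draw an application sample with CW/CM/TM/TW groups from one site.

    Cis groups follow the cohort's generative law.  Transgender TIV is drawn
    from the own-sex distribution (``sex_matched``) or from a Normal centred
    at the midpoint of the sex means (``intermediate``).  The sex-typed
    feature pattern of transgender subjects is mixed toward gender identity by
    ``pattern_alignment`` (0 = follows sex, 1 = follows gender identity).
    """
    structure = _build_structure(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))

    groups = (
        ("CW", scenario.n_cw), ("CM", scenario.n_cm),
        ("TM", scenario.n_tm), ("TW", scenario.n_tw),
    )
    group = np.concatenate([[g] * c for g, c in groups]) if any(c for _, c in groups) else np.array([], str)
    n_total = len(group)
    if n_total == 0:
        raise ValueError("scenario has zero subjects")
    sex = np.where(np.isin(group, ["CW", "TM"]), "F", "M")
    is_trans = np.isin(group, ["TM", "TW"])

    mid = 0.5 * (config.tiv_mean_female + config.tiv_mean_male)
    own_mean = np.where(sex == "F", config.tiv_mean_female, config.tiv_mean_male)
    tiv_mean = np.where(is_trans & (scenario.kind == "intermediate"), mid, own_mean)
    tiv = np.clip(rng.normal(tiv_mean, config.tiv_sd), 1.0, None)
    age = rng.uniform(config.age_range[0], config.age_range[1], size=n_total)

    sexsign = np.where(sex == "M", 1.0, -1.0)
    # gender identity sign: TM identify male (+1), TW female (-1); cis = sexsign
    gendersign = np.where(np.isin(group, ["CM", "TM"]), 1.0, -1.0)
    a = scenario.pattern_alignment
    pattern_sign = np.where(is_trans, (1 - a) * sexsign + a * gendersign, sexsign)

    site_index = np.full(n_total, config.n_sites)  # the reserved application site
    noise = rng.normal(0.0, config.noise_sd, size=(n_total, config.n_features))
    # scale relative to the training pool's TIV reference, not this small sample
    pool_mean = 0.5 * (config.tiv_mean_female + config.tiv_mean_male)
    X = synthesize_features(
        structure, config, tiv, age, pattern_sign, site_index, noise,
        pool_mean_tiv=pool_mean,
        mean_age=0.5 * (config.age_range[0] + config.age_range[1]),
    )
    ids = [f"A{i:05d}" for i in range(n_total)]
    sites = [_APP_SITE] * n_total
    return _assemble(ids, sites, sex, group, age, tiv, X)
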