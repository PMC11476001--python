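"""Simulated nodule cohorts with prescribed group means and SDs.

The real screening cohort behind the vasculature analysis is not public, so
cohort feature tables are simulated.  Two generators are provided:

``simulate_cohort``
    draws a benign and a malignant group whose per-feature means and SDs
    match a :class:`CohortSpec` (defaults reproduce the published group
    moments for the 18 band features and the demographics, plus realistic
    choices for CT-derived nodule characteristics).  Features with physical
    bounds (counts >= 0, tortuosity >= 1, ratios in [0, 1]) are drawn from
    exactly moment-matched bounded families — negative binomial for counts,
    (shifted) gamma or scaled beta for continuous bounded features — so
    sample moments converge to the requested moments as n grows despite the
    bounds.  Band counts/volumes are built
    cumulatively (band-10 value = band-5 value + a non-negative increment),
    which enforces the physical nesting of the distance bands within every
    subject.

``simulate_logit_cohort``
    draws features from pooled moments and assigns labels through a logistic
    model on chosen standardized features — the controlled-effect mode used
    for parameter-recovery and null experiments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureDef",
    "CohortSpec",
    "default_cohort_spec",
    "simulate_cohort",
    "simulate_logit_cohort",
    "VASC_FEATURES",
    "DEMOGRAPHIC_FEATURES",
    "NODULE_FEATURES",
]

_BAND_RE = re.compile(r"^(artery|vein)(5|10|15)_(count|volume)$")

# published group moments, (malignant mean, sd), (benign mean, sd);
# the 15 mm vein rows are printed as "vein10_*" in the source table but are
# unambiguously the 15 mm band (means rise 10.09 -> 16.77), emitted as vein15_*
VASC_FEATURES: dict[str, dict] = {
    "artery5_count": {"malignant": (5.39, 4.35), "benign": (1.67, 2.18)},
    "artery5_volume": {"malignant": (0.34, 0.61), "benign": (0.08, 0.13)},
    "artery5_tortuosity": {"malignant": (1.06, 0.08), "benign": (1.04, 0.16)},
    "artery10_count": {"malignant": (10.68, 9.67), "benign": (4.86, 4.61)},
    "artery10_volume": {"malignant": (0.85, 1.21), "benign": (0.28, 0.36)},
    "artery10_tortuosity": {"malignant": (1.07, 0.07), "benign": (1.06, 0.15)},
    "artery15_count": {"malignant": (18.70, 18.26), "benign": (11.51, 10.78)},
    "artery15_volume": {"malignant": (1.68, 2.14), "benign": (0.74, 0.89)},
    "artery15_tortuosity": {"malignant": (1.08, 0.07), "benign": (1.06, 0.14)},
    "vein5_count": {"malignant": (5.38, 4.08), "benign": (2.17, 3.24)},
    "vein5_volume": {"malignant": (0.33, 0.40), "benign": (0.09, 0.14)},
    "vein5_tortuosity": {"malignant": (1.06, 0.08), "benign": (1.04, 0.14)},
    "vein10_count": {"malignant": (10.09, 9.10), "benign": (4.85, 5.75)},
    "vein10_volume": {"malignant": (0.80, 0.78), "benign": (0.27, 0.32)},
    "vein10_tortuosity": {"malignant": (1.06, 0.05), "benign": (1.04, 0.14)},
    "vein15_count": {"malignant": (16.77, 16.01), "benign": (9.63, 8.91)},
    "vein15_volume": {"malignant": (1.51, 1.35), "benign": (0.62, 0.62)},
    "vein15_tortuosity": {"malignant": (1.06, 0.04), "benign": (1.05, 0.14)},
}

DEMOGRAPHIC_FEATURES: dict[str, dict] = {
    "age": {"malignant": (63.13, 5.97), "benign": (66.11, 4.65)},
    "gender": {"malignant": (36 / 67, None), "benign": (48 / 79, None), "binary": True},
    "smoking_status": {"malignant": (24 / 67, None), "benign": (28 / 79, None), "binary": True},
    "pack_years": {"malignant": (45.62, 24.58), "benign": (50.33, 21.56)},
    "BMI": {"malignant": (26.58, 4.14), "benign": (28.57, 4.71)},
}

# CT-derived nodule characteristics: group moments are this package's own
# realistic defaults (the source cohort reports none), shaped so that larger,
# more irregular, less calcified nodules are malignant and the 8-20 mm subset
# holds roughly half the cohort
NODULE_FEATURES: dict[str, dict] = {
    "tumor_mean_diameter": {
        "malignant": (17.0, 7.5),
        "benign": (8.5, 4.0),
        "lower": 2.39,
        "upper": 39.5,
    },
    "tumor_density": {"malignant": (-50.0, 150.0), "benign": (-150.0, 250.0), "lower": -np.inf},
    "tumor_cavitiy_ratio": {"malignant": (0.03, 0.05), "benign": (0.015, 0.03), "upper": 1.0},
    "tumor_ground_glass_ratio": {"malignant": (0.15, 0.18), "benign": (0.25, 0.28), "upper": 1.0},
    "tumor_fat_ratio": {"malignant": (0.01, 0.02), "benign": (0.012, 0.02), "upper": 1.0},
    "solidness": {"malignant": (0.72, 0.22), "benign": (0.58, 0.3), "upper": 1.0},
    "tumor_cal_volume": {"malignant": (0.01, 0.04), "benign": (0.05, 0.1)},
    "tumor_AgatstonCal": {"malignant": (5.0, 15.0), "benign": (20.0, 40.0)},
}


@dataclass
class FeatureDef:
    """One simulated feature: per-group (mean, sd), bounds, and type flags."""

    name: str
    malignant: tuple[float, float | None]
    benign: tuple[float, float | None]
    lower: float = 0.0
    upper: float = np.inf
    integer: bool = False
    binary: bool = False

    def moments(self, group: str) -> tuple[float, float | None]:
        return self.malignant if group == "malignant" else self.benign


def _build_defs(table: dict[str, dict], **overrides) -> list[FeatureDef]:
    defs = []
    for name, entry in table.items():
        kwargs = dict(
            name=name,
            malignant=tuple(entry["malignant"]),
            benign=tuple(entry["benign"]),
            lower=entry.get("lower", 0.0),
            upper=entry.get("upper", np.inf),
            binary=entry.get("binary", False),
        )
        if name.endswith("_count"):
            kwargs["integer"] = True
        if name.endswith("_tortuosity"):
            # physical range for vessel-branch tortuosity: >= 1 by definition
            # and bounded (a semicircular branch is ~1.57; 2 is already an
            # extreme); an unbounded marginal would emit nonphysical outliers
            kwargs["lower"] = 1.0
            kwargs["upper"] = 2.0
        kwargs.update(overrides)
        defs.append(FeatureDef(**kwargs))
    return defs


@dataclass
class CohortSpec:
    """Cohort sizes, per-feature group moments, and the correlation level."""

    n_malignant: int = 69
    n_benign: int = 79
    features: list[FeatureDef] = field(default_factory=list)
    correlation: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_malignant, self.n_benign) < 2:
            raise ValueError("need at least 2 subjects per group")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must lie in [0, 1)")
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            raise ValueError("duplicate feature names in spec")

    def feature(self, name: str) -> FeatureDef:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


def default_cohort_spec(
    n_malignant: int = 69, n_benign: int = 79, correlation: float = 0.3, seed: int | None = None
) -> CohortSpec:
    """The study-conditions spec: published vasculature/demographic moments
    plus this package's nodule-characteristic defaults."""
    defs = (
        _build_defs(VASC_FEATURES)
        + _build_defs(DEMOGRAPHIC_FEATURES)
        + _build_defs(NODULE_FEATURES)
    )
    return CohortSpec(n_malignant, n_benign, defs, correlation, seed)


def _ppf(
    u: np.ndarray, mean: float, sd: float, lower: float, upper: float, integer: bool
) -> np.ndarray:
    """Quantile transform matching the requested mean/SD under the bounds.

    The published group moments are strongly overdispersed (SD > mean for
    several non-negative features), which no zero-truncated normal can attain,
    so the marginal family is chosen by feature type — all with exact moment
    matching: negative binomial for overdispersed counts, (shifted) gamma for
    lower-bounded continuous features, scaled beta under two-sided bounds, and
    plain normal when unbounded.
    """
    if sd == 0:
        return np.full_like(u, mean)
    var = sd**2
    if integer and lower == 0 and var > mean:
        r = mean**2 / (var - mean)
        p = mean / var
        return stats.nbinom.ppf(u, r, p)
    if np.isfinite(upper):
        span = upper - lower
        m, v = (mean - lower) / span, var / span**2
        if v >= m * (1 - m):
            raise ValueError(
                f"infeasible moments: sd {sd} too large for range ({lower}, {upper})"
            )
        conc = m * (1 - m) / v - 1
        vals = lower + span * stats.beta.ppf(u, m * conc, (1 - m) * conc)
    elif np.isfinite(lower):
        shape = ((mean - lower) / sd) ** 2
        scale = var / (mean - lower)
        vals = lower + stats.gamma.ppf(u, shape, scale=scale)
    else:
        vals = stats.norm.ppf(u, loc=mean, scale=sd)
    return np.round(vals) if integer else vals


def _primitives(spec: CohortSpec) -> list[tuple[FeatureDef, str | None]]:
    """Expand band-count/volume families into (band-5 base, increments).

    Returns (definition, total_name) pairs: for increments ``total_name`` is
    the cumulative column the increment builds; for plain features it is None.
    """
    by_name = {f.name: f for f in spec.features}
    handled: set[str] = set()
    prims: list[tuple[FeatureDef, str | None]] = []
    for f in spec.features:
        m = _BAND_RE.match(f.name)
        if not m:
            prims.append((f, None))
            continue
        comp, _, metric = m.groups()
        family = [f"{comp}{d}_{metric}" for d in (5, 10, 15)]
        if not all(n in by_name for n in family):
            prims.append((f, None))  # incomplete family: treat independently
            continue
        if family[0] in handled:
            continue
        handled.update(family)
        prev = by_name[family[0]]
        prims.append((prev, None))
        for name_prev, name_cur in zip(family, family[1:]):
            cur = by_name[name_cur]
            inc_m, inc_b = [], []
            for group in ("malignant", "benign"):
                m_prev, s_prev = by_name[name_prev].moments(group)
                m_cur, s_cur = cur.moments(group)
                if m_cur < m_prev or (s_cur or 0) < (s_prev or 0):
                    raise ValueError(
                        f"infeasible moments: {name_cur} must dominate {name_prev} "
                        "in both mean and SD (cumulative bands)"
                    )
                inc = (m_cur - m_prev, float(np.sqrt(s_cur**2 - s_prev**2)))
                (inc_m if group == "malignant" else inc_b).append(inc)
            prims.append(
                (
                    replace(cur, name=f"_inc_{name_cur}", malignant=inc_m[0], benign=inc_b[0]),
                    name_cur,
                )
            )
    return prims


def _draw_group(
    spec: CohortSpec, group: str, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    prims = _primitives(spec)
    p = len(prims)
    rho = spec.correlation
    shared = rng.standard_normal((n, 1))
    eps = rng.standard_normal((n, p))
    z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * eps
    # band increments stay independent of their own base so the cumulative
    # totals keep the prescribed variance
    is_inc = np.array([total is not None for _, total in prims])
    z[:, is_inc] = eps[:, is_inc]
    u = stats.norm.cdf(z)
    # keep the copula away from the exact 0/1 tails
    u = np.clip(u, 1e-12, 1 - 1e-12)

    cols: dict[str, np.ndarray] = {}
    for k, (fdef, total_name) in enumerate(prims):
        mean, sd = fdef.moments(group)
        if fdef.binary:
            vals = (u[:, k] < mean).astype(float)
        elif sd == 0 or mean == fdef.lower:
            if mean < fdef.lower or (mean == fdef.lower and sd):
                raise ValueError(f"infeasible moments: {fdef.name} mean {mean} at bound {fdef.lower}")
            vals = np.full(n, mean)
        else:
            if mean < fdef.lower:
                raise ValueError(f"infeasible moments: {fdef.name} mean {mean} < {fdef.lower}")
            vals = _ppf(u[:, k], mean, float(sd), fdef.lower, fdef.upper, fdef.integer)
        if total_name is None:
            cols[fdef.name] = vals
        else:
            base = total_name.replace("15_", "10_") if "15_" in total_name else total_name.replace("10_", "5_")
            cols[total_name] = cols[base] + vals
    return pd.DataFrame(cols)


def simulate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> pd.DataFrame:
    """Simulate a two-group cohort table matching the requested group moments.

    Returns one row per nodule with a ``malignant`` label column in {0, 1};
    rows are shuffled deterministically.  Within each subject the band
    counts/volumes are non-decreasing across 5 -> 10 -> 15 mm by construction.
    """
    spec = spec or default_cohort_spec()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    groups = []
    for group, n in (("malignant", spec.n_malignant), ("benign", spec.n_benign)):
        df = _draw_group(spec, group, n, rng)
        df["malignant"] = int(group == "malignant")
        groups.append(df)
    out = pd.concat(groups, ignore_index=True)
    out = _derive_nodule_geometry(out, rng)
    order = rng.permutation(len(out))
    return out.iloc[order].reset_index(drop=True)


def _derive_nodule_geometry(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Geometry columns derived from the simulated mean diameter."""
    if "tumor_mean_diameter" not in df.columns:
        return df
    d = df["tumor_mean_diameter"].to_numpy()
    n = len(df)
    df = df.copy()
    # max Feret diameter exceeds the equivalent-sphere diameter
    df["tumor_max_diameter"] = d * (1.0 + np.abs(rng.normal(0.25, 0.1, n)))
    vol_mm3 = np.pi / 6.0 * d**3 * np.exp(rng.normal(0.0, 0.05, n))
    df["tumor_volume"] = vol_mm3 / 1000.0  # cm^3
    surface_excess = 1.0 + np.abs(rng.normal(0.2, 0.1, n))
    df["tumor_surface_area"] = np.pi * d**2 * surface_excess
    df["tumor_irregularity"] = df["tumor_surface_area"] / vol_mm3
    return df


def simulate_logit_cohort(
    n: int,
    effects: dict[str, float] | None = None,
    seed: int | None = None,
    spec: CohortSpec | None = None,
    intercept: float = 0.0,
) -> pd.DataFrame:
    """Features from pooled moments; labels from a logistic model.

    ``effects`` maps feature name -> log-odds per SD of that feature; an empty
    mapping yields a label-independent (null) cohort with ~50% prevalence.
    """
    spec = spec or default_cohort_spec()
    pooled = []
    for f in spec.features:
        mm, ms = f.malignant
        bm, bs = f.benign
        if f.binary:
            pooled.append(replace(f, malignant=((mm + bm) / 2, None), benign=((mm + bm) / 2, None)))
        else:
            mom = ((mm + bm) / 2, (ms + bs) / 2)
            pooled.append(replace(f, malignant=mom, benign=mom))
    pooled_spec = CohortSpec(2, 2, pooled, spec.correlation)
    rng = np.random.default_rng(seed)
    df = _draw_group(pooled_spec, "benign", n, rng)
    df = _derive_nodule_geometry(df, rng)
    logit = np.full(n, float(intercept))
    for name, beta in (effects or {}).items():
        x = df[name].to_numpy(dtype=float)
        logit += beta * (x - x.mean()) / x.std(ddof=1)
    prob = 1.0 / (1.0 + np.exp(-logit))
    df["malignant"] = (rng.uniform(size=n) < prob).astype(int)
    return df
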