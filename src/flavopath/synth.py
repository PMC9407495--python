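"""Synthetic cohorts with a known climate -> flavonoid -> peel-color structure.

The generator realizes a linear-Gaussian causal chain: standardized altitude
drives the annual climate factors, standardized climate drives flavonoid
contents, and peel color (CIELAB) receives both direct climate effects and
flavonoid-mediated effects. Every nonzero generating path is recorded in a
:class:`SyntheticTruth` on the standardized scale, derived analytically from
the model-implied covariance, so downstream estimators (correlation
screening, stepwise selection, path decomposition, SEM) can be scored
against ground truth.

Internally all structural equations are written in "model units": each
climate factor is analytically standardized, flavonoids and color axes are
generated as linear combinations of standardized parents plus independent
Gaussian noise, then shifted/scaled into mg/g and CIELAB units. The
raw-unit affine maps cancel from every standardized quantity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .sample_io import (
    ANALYTE_CODES,
    CLIMATE_CODES,
    COLOR_CODES,
    ColorTriple,
    SampleRecord,
    SampleTable,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "default_config",
    "generate",
    "truth_effects",
]

GROUP_LETTERS = "ABCDEFGHIJ"


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class SyntheticConfig:
    """Full parameterization of the generative model.

    ``climate_coeffs`` maps each climate code to ``(intercept, slope,
    noise_sd)`` in raw units, the slope being per standard deviation of
    altitude. ``flavonoid_loadings`` / ``color_*`` coefficients act on
    standardized parents; ``*_loc`` / ``*_scale`` place the standardized
    responses on their raw scales (mg/g, CIELAB).
    """

    n_groups: int = 6
    samples_per_group: int | tuple[int, ...] = (5, 5, 4, 4, 4, 4)
    altitude_range: tuple[float, float] = (201.0, 2188.0)
    seed: int = 0
    climate_coeffs: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    flavonoid_loadings: dict[str, dict[str, float]] = field(default_factory=dict)
    flavonoid_noise_sd: dict[str, float] = field(default_factory=dict)
    flavonoid_loc: dict[str, float] = field(default_factory=dict)
    flavonoid_scale: dict[str, float] = field(default_factory=dict)
    color_direct_climate: dict[str, dict[str, float]] = field(default_factory=dict)
    color_flavonoid_loadings: dict[str, dict[str, float]] = field(default_factory=dict)
    color_noise_sd: dict[str, float] = field(default_factory=dict)
    color_loc: dict[str, float] = field(default_factory=dict)
    color_scale: dict[str, float] = field(default_factory=dict)

    def group_sizes(self) -> tuple[int, ...]:
        if isinstance(self.samples_per_group, int):
            return (self.samples_per_group,) * self.n_groups
        return tuple(self.samples_per_group)

    def validate(self) -> None:
        sizes = self.group_sizes()
        if len(sizes) != self.n_groups or any(s < 1 for s in sizes):
            raise ConfigError("samples_per_group must give >= 1 sample per group")
        lo, hi = self.altitude_range
        if not lo < hi:
            raise ConfigError("altitude_range must satisfy min < max")
        for code, (_, _, sd) in self.climate_coeffs.items():
            if sd < 0:
                raise ConfigError(f"negative climate noise SD for {code}")
        for code, sd in {**self.flavonoid_noise_sd, **self.color_noise_sd}.items():
            if sd < 0:
                raise ConfigError(f"negative noise SD for {code}")

    def zero_noise(self) -> "SyntheticConfig":
        """Copy of this config with every noise SD set to zero."""
        return replace(
            self,
            climate_coeffs={k: (i, s, 0.0) for k, (i, s, _) in self.climate_coeffs.items()},
            flavonoid_noise_sd={k: 0.0 for k in self.flavonoid_noise_sd},
            color_noise_sd={k: 0.0 for k in self.color_noise_sd},
        )


@dataclass
class SyntheticTruth:
    """Standardized generating paths and the two-edge indirect products.

    ``standardized_paths`` maps (source, target) to the standardized
    coefficient; ``implied_indirects`` maps (climate, color-axis, mediator)
    to the product of the two constituent standardized paths. ``implied_cov``
    is the model-implied covariance over ``variables`` in model units
    (altitude and climate standardized, flavonoids/color pre-affine).
    """

    standardized_paths: dict[tuple[str, str], float]
    implied_indirects: dict[tuple[str, str, str], float]
    variables: tuple[str, ...] = ()
    implied_cov: np.ndarray | None = None

    def implied_correlation(self, x: str, y: str) -> float:
        """Closed-form model-implied Pearson correlation between two codes."""
        if self.implied_cov is None:
            raise ValueError("truth carries no implied covariance")
        i, j = self.variables.index(x), self.variables.index(y)
        c = self.implied_cov
        return float(c[i, j] / np.sqrt(c[i, i] * c[j, j]))

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "paths": [
                {"source": s, "target": t, "value": v}
                for (s, t), v in sorted(self.standardized_paths.items())
            ],
            "indirects": [
                {"source": s, "target": t, "mediator": m, "value": v}
                for (s, t, m), v in sorted(self.implied_indirects.items())
            ],
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path


def default_config() -> SyntheticConfig:
    """The reference study design: 26 samples in 6 contiguous-altitude
    groups spanning 201-2188 m, temperature decreasing and wind increasing
    with altitude, and structural coefficients seeded from the fitted color
    models (e.g. -0.50 and 0.41 into cyanidin 3-O-glucoside, 0.88 onward to
    a*; 0.45 and 0.75 along the lightness chain)."""
    climate = {
        #        intercept  slope/SD(alt)  noise SD   (raw units)
        "X_AMT":  (12.0,  -4.0,  2.0),
        "X_AMAT": (18.0,  -4.5,  2.2),
        "X_AMIT": (7.0,   -3.5,  1.8),
        "X_RH":   (60.0,  -6.0,  5.0),
        "X_AAP":  (600.0, -150.0, 120.0),
        "X_MW":   (2.0,    0.5,  0.35),
        "X_MAW":  (8.0,    1.5,  1.2),
        "X_EW":   (15.0,   2.5,  2.2),
        "X_ASD":  (2100.0, -120.0, 150.0),
        "X_ASP":  (50.0,   3.0,  4.0),
    }
    loadings: dict[str, dict[str, float]] = {
        "Y_HY":  {"X_RH": -0.72},
        "Y_LU":  {"X_AMAT": -0.35, "X_MAW": 0.30},
        "Y_KP":  {"X_MAW": 0.15},
        "Y_QI":  {"X_AMT": -0.44, "X_AMAT": -0.53, "X_MW": -0.30},
        "Y_C":   {},
        "Y_RU":  {"X_AMT": 0.25},
        "Y_CA":  {"X_AMAT": -0.35, "X_MAW": 0.30},
        "Y_QU":  {"X_AMAT": -0.35, "X_MAW": 0.30},
        "Y_HE":  {"X_AMT": 0.25},
        "Y_AP":  {"X_AMAT": -0.72, "X_ASD": -0.52},
        "Y_PH":  {"X_AMAT": -0.66, "X_MAW": 0.35},
        "Y_PG":  {"X_AMAT": -0.45, "X_MAW": 0.45},
        "Y_CGC": {"X_AMAT": -0.50, "X_MAW": 0.41},
        "Y_CSA": {"X_AMAT": -0.56},
        "Y_CGT": {"X_AMAT": -0.44},
    }
    noise = {
        "Y_HY": 0.60, "Y_LU": 0.80, "Y_KP": 0.95, "Y_QI": 0.50, "Y_C": 1.00,
        "Y_RU": 0.95, "Y_CA": 0.80, "Y_QU": 0.80, "Y_HE": 0.95, "Y_AP": 0.60,
        "Y_PH": 0.55, "Y_PG": 0.55, "Y_CGC": 0.55, "Y_CSA": 0.80, "Y_CGT": 0.85,
    }
    # raw-scale placement: locations near the measured means, scales kept
    # small relative to location so contents stay positive (>5 sigma margin)
    loc = {
        "Y_HY": 14.0, "Y_LU": 2.0, "Y_KP": 1.7, "Y_QI": 20.0, "Y_C": 8.0,
        "Y_RU": 7.7, "Y_CA": 8.0, "Y_QU": 2.0, "Y_HE": 4.4, "Y_AP": 2.6,
        "Y_PH": 5.3, "Y_PG": 5.4, "Y_CGC": 8.2, "Y_CSA": 6.5, "Y_CGT": 8.5,
    }
    scale = {k: v / 8.0 for k, v in loc.items()}
    color_direct = {
        "L": {"X_MAW": 0.21},
        "a": {"X_AMAT": -0.46, "X_MAW": 0.36},
        "b": {"X_AAP": 0.16, "X_AMT": 0.10, "X_AMAT": 0.06},
    }
    color_flav = {
        "L": {"Y_PG": 0.75},
        "a": {"Y_CGC": 0.88},
        "b": {"Y_QI": -0.77},
    }
    return SyntheticConfig(
        climate_coeffs=climate,
        flavonoid_loadings=loadings,
        flavonoid_noise_sd=noise,
        flavonoid_loc=loc,
        flavonoid_scale=scale,
        color_direct_climate=color_direct,
        color_flavonoid_loadings=color_flav,
        color_noise_sd={"L": 0.35, "a": 0.30, "b": 0.30},
        color_loc={"L": 83.0, "a": 100.0, "b": 35.0},
        color_scale={"L": 4.0, "a": 25.0, "b": 10.0},
    )


def _model_matrices(config: SyntheticConfig):
    """Coefficient matrix A (child rows x parent cols) and noise variances
    psi over the model-unit variable order [altitude, climate..., flavonoids...,
    color...]."""
    variables = ["altitude"] + list(CLIMATE_CODES) + list(ANALYTE_CODES) + list(COLOR_CODES)
    idx = {v: i for i, v in enumerate(variables)}
    p = len(variables)
    A = np.zeros((p, p))
    psi = np.zeros(p)
    psi[idx["altitude"]] = 1.0  # standardized driver
    for code in CLIMATE_CODES:
        _, slope, sd = config.climate_coeffs[code]
        total = float(np.hypot(slope, sd))
        if total == 0:
            raise ConfigError(f"climate factor {code} has zero slope and noise")
        s = slope / total  # standardized altitude -> climate path
        A[idx[code], idx["altitude"]] = s
        psi[idx[code]] = 1.0 - s**2
    for code in ANALYTE_CODES:
        for parent, coef in config.flavonoid_loadings.get(code, {}).items():
            A[idx[code], idx[parent]] = coef
        psi[idx[code]] = config.flavonoid_noise_sd.get(code, 1.0) ** 2
    for axis in COLOR_CODES:
        for parent, coef in config.color_direct_climate.get(axis, {}).items():
            A[idx[axis], idx[parent]] = coef
        for parent, coef in config.color_flavonoid_loadings.get(axis, {}).items():
            A[idx[axis], idx[parent]] = coef
        psi[idx[axis]] = config.color_noise_sd.get(axis, 1.0) ** 2
    return variables, idx, A, psi


def _implied_cov(A: np.ndarray, psi: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(np.eye(len(psi)) - A)
    return inv @ np.diag(psi) @ inv.T


def _build_truth(config: SyntheticConfig) -> SyntheticTruth:
    variables, idx, A, psi = _model_matrices(config)
    cov = _implied_cov(A, psi)
    sd = np.sqrt(np.diag(cov))
    paths: dict[tuple[str, str], float] = {}
    for child in range(len(variables)):
        for parent in range(len(variables)):
            if A[child, parent] != 0.0:
                paths[(variables[parent], variables[child])] = float(
                    A[child, parent] * sd[parent] / sd[child]
                )
    indirects: dict[tuple[str, str, str], float] = {}
    for climate in CLIMATE_CODES:
        for axis in COLOR_CODES:
            for mediator in ANALYTE_CODES:
                first = paths.get((climate, mediator))
                second = paths.get((mediator, axis))
                if first is not None and second is not None:
                    indirects[(climate, axis, mediator)] = first * second
    return SyntheticTruth(
        standardized_paths=paths,
        implied_indirects=indirects,
        variables=tuple(variables),
        implied_cov=cov,
    )


def generate(config: SyntheticConfig | None = None,
             seed: int | None = None) -> tuple[SampleTable, SyntheticTruth]:
    """Draw one cohort. Deterministic for a given config and seed; ``seed``
    overrides ``config.seed`` when given."""
    config = config or default_config()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sizes = config.group_sizes()
    n = sum(sizes)
    lo, hi = config.altitude_range

    # groups occupy contiguous altitude bands, highest band first (group A)
    edges = np.linspace(hi, lo, config.n_groups + 1)
    altitudes = []
    groups = []
    ids = []
    for g, size in enumerate(sizes):
        top, bottom = edges[g], edges[g + 1]
        alt = rng.uniform(min(bottom, top), max(bottom, top), size=size)
        altitudes.extend(np.sort(alt)[::-1])
        letter = GROUP_LETTERS[g]
        groups.extend([letter] * size)
        ids.extend([f"{letter}{k + 1}" for k in range(size)])
    altitudes = np.asarray(altitudes)
    z_alt = (altitudes - altitudes.mean()) / altitudes.std(ddof=0)

    climate_raw: dict[str, np.ndarray] = {}
    climate_std: dict[str, np.ndarray] = {}
    for code in CLIMATE_CODES:
        intercept, slope, sd = config.climate_coeffs[code]
        raw = intercept + slope * z_alt + rng.normal(0.0, sd, size=n)
        climate_raw[code] = raw
        climate_std[code] = (raw - intercept) / float(np.hypot(slope, sd))

    flav_std: dict[str, np.ndarray] = {}
    flav_raw: dict[str, np.ndarray] = {}
    for code in ANALYTE_CODES:
        value = np.zeros(n)
        for parent, coef in config.flavonoid_loadings.get(code, {}).items():
            value = value + coef * climate_std[parent]
        value = value + rng.normal(0.0, config.flavonoid_noise_sd.get(code, 1.0), size=n)
        flav_std[code] = value
        flav_raw[code] = (config.flavonoid_loc.get(code, 10.0)
                          + config.flavonoid_scale.get(code, 1.0) * value)

    color_raw: dict[str, np.ndarray] = {}
    for axis in COLOR_CODES:
        value = np.zeros(n)
        for parent, coef in config.color_direct_climate.get(axis, {}).items():
            value = value + coef * climate_std[parent]
        for parent, coef in config.color_flavonoid_loadings.get(axis, {}).items():
            value = value + coef * flav_std[parent]
        value = value + rng.normal(0.0, config.color_noise_sd.get(axis, 1.0), size=n)
        color_raw[axis] = (config.color_loc.get(axis, 0.0)
                           + config.color_scale.get(axis, 1.0) * value)

    records = []
    for i in range(n):
        records.append(
            SampleRecord(
                sample_id=ids[i],
                group=groups[i],
                altitude=float(altitudes[i]),
                flavonoids={c: float(flav_raw[c][i]) for c in ANALYTE_CODES},
                color=ColorTriple(*(float(color_raw[ax][i]) for ax in COLOR_CODES)),
                climate={c: float(climate_raw[c][i]) for c in CLIMATE_CODES},
            )
        )
    return SampleTable(records), _build_truth(config)


def _dag_paths(paths: Mapping[tuple[str, str], float],
               source: str, target: str) -> list[list[str]]:
    """All directed paths source -> ... -> target over the truth edge set."""
    children: dict[str, list[str]] = {}
    for (s, t) in paths:
        children.setdefault(s, []).append(t)
    out: list[list[str]] = []

    def walk(node: str, acc: list[str]) -> None:
        if node == target and len(acc) > 1:
            out.append(list(acc))
            return
        for nxt in sorted(children.get(node, [])):
            walk(nxt, acc + [nxt])

    walk(source, [source])
    return out


def truth_effects(truth: SyntheticTruth, source: str, target: str
                  ) -> tuple[float, float, float]:
    """(direct, indirect, total) standardized effect of ``source`` on
    ``target`` under the generating model; the indirect part sums the
    coefficient products over every mediated directed path."""
    known = set()
    for s, t in truth.standardized_paths:
        known.add(s)
        known.add(t)
    for code in (source, target):
        if code not in known:
            raise KeyError(f"code {code!r} unknown to the truth")
    direct = truth.standardized_paths.get((source, target), 0.0)
    indirect = 0.0
    for chain in _dag_paths(truth.standardized_paths, source, target):
        if len(chain) == 2:
            continue
        prod = 1.0
        for a, b in zip(chain, chain[1:]):
            prod *= truth.standardized_paths[(a, b)]
        indirect += prod
    return direct, indirect, direct + indirect
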