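"""Calibration table loading and truncated-normal moment matching.

The cohort simulator is calibrated to printed group-level moments
(mean ± SD) and category proportions. Because most calibrated quantities
have hard physiologic lower bounds, marginals are truncated normals whose
*post-truncation* mean and SD are re-standardized to match the calibration
targets (within 2%), rather than naively plugging the printed moments into
the untruncated parent.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import optimize
from scipy.special import ndtr, ndtri
from scipy.stats import truncnorm

CALIBRATION_VERSION = "calibration_v1"

GROUPS = ("nonpad", "pad")
FEATURE_KEYS = ("delta_hbo", "hf", "vo2", "tp")
PRESSURES = (60, 100)


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class TruncatedNormalSpec:
    """A truncated normal whose truncated moments equal (mean, sd).

    ``mu``/``sigma`` are the parent parameters found by the matching solver;
    ``lower``/``upper`` are the truncation bounds in data units.
    """

    mean: float
    sd: float
    lower: float
    upper: float
    mu: float
    sigma: float

    def _ab(self) -> tuple[float, float]:
        a = (self.lower - self.mu) / self.sigma
        b = (self.upper - self.mu) / self.sigma
        return a, b

    def ppf(self, q: np.ndarray | float) -> np.ndarray | float:
        if self.sigma == 0:  # degenerate: every quantile is the mean
            return np.full_like(np.asarray(q, dtype=float), self.mean) if np.ndim(q) else self.mean
        a, b = self._ab()
        fa, fb = ndtr(a), ndtr(b)
        return self.mu + self.sigma * ndtri(fa + np.asarray(q) * (fb - fa))

    def rvs(self, rng: np.random.Generator, size: int | None = None):
        return self.ppf(rng.uniform(size=size))

    def from_latent(self, z: np.ndarray | float):
        """Map standard-normal latents through the Gaussian copula.

        Preserves the truncated-normal marginal exactly while letting a
        shared latent factor induce cross-variable correlation.
        """
        return self.ppf(ndtr(z))


def _truncated_moments(mu: float, sigma: float, lower: float, upper: float):
    a = (lower - mu) / sigma
    b = (upper - mu) / sigma
    m, v = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(m), float(np.sqrt(v))


@functools.lru_cache(maxsize=512)
def match_truncated_normal(
    mean: float, sd: float, lower: float = 0.0, upper: float = np.inf
) -> TruncatedNormalSpec:
    """Find parent (mu, sigma) so the truncated moments hit (mean, sd).

    Raises :class:`CalibrationError` when no truncated normal on
    ``[lower, upper]`` attains the requested moments within 2%; with a
    lower bound of 0 this happens when SD >= mean (the truncated family's
    coefficient of variation is bounded below 1).
    """
    if sd < 0 or not np.isfinite(mean):
        raise CalibrationError(f"invalid target moments mean={mean}, sd={sd}")
    if not (lower < upper):
        raise CalibrationError("lower bound must be below upper bound")
    if sd == 0:
        if not (lower <= mean <= upper):
            raise CalibrationError("degenerate mean outside bounds")
        return TruncatedNormalSpec(mean, 0.0, lower, upper, mean, 0.0)

    def residual(p):
        mu, log_sigma = p
        m, s = _truncated_moments(mu, np.exp(log_sigma), lower, upper)
        return [(m - mean) / sd, (s - sd) / sd]

    best = None
    for mu0 in (mean, mean - sd, mean - 2 * sd, mean - 4 * sd):
        for s0 in (sd, 1.5 * sd, 3 * sd):
            sol = optimize.root(residual, [mu0, np.log(s0)], method="hybr")
            err = float(np.max(np.abs(residual(sol.x))))
            if best is None or err < best[0]:
                best = (err, sol.x)
            if err < 1e-8:
                break
        if best[0] < 1e-8:
            break
    err, (mu, log_sigma) = best
    if err > 0.02:
        raise CalibrationError(
            f"no truncated normal on [{lower}, {upper}] matches mean={mean}, "
            f"sd={sd} within 2% (best relative error {err:.3g})"
        )
    return TruncatedNormalSpec(mean, sd, lower, upper, float(mu), float(np.exp(log_sigma)))


def load_calibration(version: str = CALIBRATION_VERSION) -> dict:
    """Read the shipped key-value calibration table.

    Returns ``{"version", "features": {group: {key: value}},
    "covariates": {group: {key: value}}}``.
    """
    text = resources.files("dvoscope.data").joinpath(f"{version}.tsv").read_text()
    table: dict = {"version": version, "features": {}, "covariates": {}}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise CalibrationError(f"{version}.tsv line {lineno}: expected 4 columns")
        section, group, key, value = parts
        if section not in table or group not in GROUPS:
            raise CalibrationError(f"{version}.tsv line {lineno}: bad section/group")
        table[section].setdefault(group, {})[key] = float(value)
    for section in ("features", "covariates"):
        for group in GROUPS:
            if group not in table[section]:
                raise CalibrationError(f"missing {section} for group {group}")
    return table


def feature_moments(table: dict, group: str, key: str, pressure: int) -> tuple[float, float]:
    vals = table["features"][group]
    return vals[f"{key}_{pressure}_mean"], vals[f"{key}_{pressure}_sd"]
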