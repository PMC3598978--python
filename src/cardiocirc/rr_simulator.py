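"""Random RR-series generation from the circadian model.

A simulated RR series combines the deterministic circadian mean with a
stationary autoregressive residual on the log scale:

1. draw a stationary AR(P) noise sequence eps_t with Gaussian
   innovations of SD tau;
2. evaluate the circadian mean log RR at the chosen time points;
3. add the two and exponentiate.

The AR order found to capture the long memory of within-subject RR
residuals at a 1-minute sampling step is large (P = 180, i.e. a 3-hour
lag window), with innovation SD tau = 0.096.  The individual alpha
coefficients of that fit are not part of the published summary, so
:func:`default_ar_model` constructs a long-memory alpha vector from the
truncated AR(inf) expansion of a fractional-differencing filter,
calibrating the memory parameter so the stationary marginal SD of the
residual process equals the regression sigma (0.15) given tau = 0.096.
"""

from __future__ import annotations

import functools
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.special import gammaln

from .model_core import (CircadianCoefficients, DEFAULT_COEFFICIENTS,
                         SubjectProfile, predict_log_rr)
from .preprocessing import RRSeries

__all__ = [
    "ARModel",
    "SimulationSpec",
    "default_ar_model",
    "ar_marginal_sd",
    "max_characteristic_root",
    "simulate_ar_noise",
    "simulate_subject_rr",
    "generate_virtual_cohort",
    "uniform_grid",
]


@dataclass(frozen=True)
class ARModel:
    """Stationary AR(P) residual process on the log-RR scale.

    eps_t = sum_p alpha_p * eps_{t-p} + eta,  eta ~ N(0, tau).

    ``alphas`` has length P (P = 0 gives pure white noise); ``tau`` is
    the innovation SD.  Stationarity (all characteristic roots inside
    the unit circle of the companion form) is checked at construction
    with a warning, not a hard failure.
    """

    alphas: tuple = field(default=())
    tau: float = 0.096

    def __post_init__(self):
        object.__setattr__(
            self, "alphas",
            tuple(float(a) for a in np.atleast_1d(np.asarray(self.alphas, dtype=float))))
        if not np.all(np.isfinite(self.alphas_array)):
            raise ValueError("alpha coefficients must be finite")
        if not (np.isfinite(self.tau) and self.tau >= 0):
            raise ValueError(f"tau must be finite and >= 0, got {self.tau!r}")
        if self.order and max_characteristic_root(self) >= 1.0:
            import warnings
            warnings.warn("AR model is not stationary (characteristic root >= 1)",
                          stacklevel=2)

    @property
    def order(self) -> int:
        return len(self.alphas)

    @property
    def alphas_array(self) -> np.ndarray:
        return np.asarray(self.alphas, dtype=float)

    def to_dict(self) -> dict:
        return {"alphas": list(self.alphas), "tau": float(self.tau)}

    @classmethod
    def from_dict(cls, d: dict) -> "ARModel":
        return cls(alphas=tuple(d.get("alphas", ())), tau=float(d["tau"]))


def max_characteristic_root(ar: ARModel) -> float:
    """Largest modulus among roots of z^P - a1 z^(P-1) - ... - aP.

    < 1 means the process is stationary.
    """
    if ar.order == 0:
        return 0.0
    poly = np.concatenate(([1.0], -ar.alphas_array))
    return float(np.max(np.abs(np.roots(poly))))


def ar_marginal_sd(ar: ARModel) -> float:
    """Exact stationary marginal SD of the AR process (Yule-Walker solve)."""
    p = ar.order
    if p == 0:
        return float(ar.tau)
    a = ar.alphas_array
    # unknowns gamma_0..gamma_p; row 0: gamma_0 - sum a_j gamma_j = tau^2
    # row k (1..p): gamma_k - sum_j a_j gamma_|k-j| = 0
    A = np.zeros((p + 1, p + 1))
    A[0, 0] = 1.0
    A[0, 1:] -= a
    for k in range(1, p + 1):
        A[k, k] += 1.0
        for j in range(1, p + 1):
            A[k, abs(k - j)] -= a[j - 1]
    b = np.zeros(p + 1)
    b[0] = ar.tau ** 2
    gamma = np.linalg.solve(A, b)
    return float(np.sqrt(gamma[0]))


def _fractional_alphas(d: float, order: int) -> np.ndarray:
    # AR(inf) weights of the fractional-differencing filter (1-B)^d:
    # pi_j = d * Gamma(j - d) / (Gamma(j + 1) * Gamma(1 - d)), all positive.
    j = np.arange(1, order + 1)
    return np.exp(np.log(d) + gammaln(j - d) - gammaln(j + 1.0) - gammaln(1.0 - d))


@functools.lru_cache(maxsize=8)
def default_ar_model(order: int = 180, tau: float = 0.096,
                     target_marginal_sd: float = 0.15) -> ARModel:
    """Long-memory AR model consistent with the circadian regression.

    Alphas come from the truncated AR(inf) expansion of a fractional
    noise filter; the memory parameter d is solved by bisection so that
    the stationary marginal SD equals ``target_marginal_sd`` (the
    regression sigma) for the given innovation SD ``tau``.  Calibrated
    for a 1-minute time step.
    """
    lo, hi = 1e-3, 0.499

    def sd_at(d):
        return ar_marginal_sd(ARModel(tuple(_fractional_alphas(d, order)), tau))

    if not sd_at(lo) <= target_marginal_sd <= sd_at(hi):
        raise ValueError("target marginal SD not reachable for this tau/order")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if sd_at(mid) < target_marginal_sd:
            lo = mid
        else:
            hi = mid
    d = 0.5 * (lo + hi)
    return ARModel(tuple(_fractional_alphas(d, order)), tau)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_ar_noise(ar: ARModel, length: int, seed=None, burn_in: int | None = None):
    """Draw an approximately stationary AR(P) sequence of a given length.

    Gaussian innovations of SD tau; an initial burn-in (default
    10 * P steps, at least the order itself) is generated and discarded
    so the returned segment is effectively stationary.  Reproducible for
    a fixed integer seed; a non-stationary alpha vector is refused with
    the offending root modulus reported.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if ar.order:
        root = max_characteristic_root(ar)
        if root >= 1.0:
            raise ValueError(
                f"non-stationary AR model (largest characteristic root {root:.4f} >= 1)")
    if burn_in is None:
        burn_in = 10 * ar.order
    if ar.tau == 0.0:
        return np.zeros(length)
    rng = _as_rng(seed)
    eta = rng.normal(0.0, ar.tau, size=burn_in + length)
    if ar.order == 0:
        return eta[burn_in:]
    eps = signal.lfilter([1.0], np.concatenate(([1.0], -ar.alphas_array)), eta)
    return eps[burn_in:]


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to simulate RR series: model, noise process, time grid, seed.

    ``times`` are hours on a monotone elapsed axis (clock hour is taken
    mod 24 at evaluation); one AR transition is taken per grid point,
    so the default AR model is calibrated for 1-minute grids.
    """

    coefficients: CircadianCoefficients = DEFAULT_COEFFICIENTS
    ar: ARModel = None
    times: np.ndarray = None
    seed: int = 0

    def __post_init__(self):
        if self.ar is None:
            object.__setattr__(self, "ar", default_ar_model())
        t = np.atleast_1d(np.asarray(
            uniform_grid() if self.times is None else self.times, dtype=float))
        if t.size == 0:
            raise ValueError("times must be non-empty")
        object.__setattr__(self, "times", t)


def uniform_grid(start_hour: float = 0.0, step_minutes: float = 1.0,
                 duration_hours: float = 24.0) -> np.ndarray:
    """Uniform time grid in hours: start, start+step, ... over the duration."""
    if step_minutes <= 0:
        raise ValueError("step_minutes must be > 0")
    n = int(round(duration_hours * 60.0 / step_minutes))
    return start_hour + np.arange(n) * (step_minutes / 60.0)


def _subject_seed(root_seed: int, subject_id: str) -> np.random.SeedSequence:
    # stable per-subject child stream: root seed + CRC32 of the subject id,
    # so cohorts are reproducible and independent of simulation order
    return np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF,
                                   zlib.crc32(subject_id.encode("utf-8"))])


def simulate_subject_rr(spec: SimulationSpec, subject: SubjectProfile) -> RRSeries:
    """Simulate one subject's RR series on the spec's time grid.

    rr(t) = exp(mean log RR(subject, t) + eps_t), with eps the AR noise
    aligned one step per grid point.  Deterministic per (seed, subject id).
    """
    rng = np.random.default_rng(_subject_seed(spec.seed, subject.subject_id))
    eps = simulate_ar_noise(spec.ar, len(spec.times), seed=rng)
    mu = predict_log_rr(spec.coefficients, subject, spec.times)
    rr = np.exp(np.asarray(mu) + eps)
    t = spec.times
    elapsed = t if (t.size < 2 or np.all(np.diff(t) >= 0)) else None
    return RRSeries(subject, np.mod(t, 24.0), rr, elapsed_hours=elapsed)


def generate_virtual_cohort(n: int, sex_ratio: float = 0.5,
                            age_low: float = 20.0, age_high: float = 50.0,
                            seed=0, id_prefix: str = "virt") -> list[SubjectProfile]:
    """Virtual cohort with a deterministic sex split and uniform ages.

    Exactly round(n * sex_ratio) males; ages drawn uniformly on
    [age_low, age_high].  Reproducible per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= sex_ratio <= 1.0:
        raise ValueError("sex_ratio must be in [0, 1]")
    if age_low > age_high or age_low < 0:
        raise ValueError("need 0 <= age_low <= age_high")
    rng = _as_rng(seed)
    n_male = int(round(n * sex_ratio))
    sexes = [1] * n_male + [0] * (n - n_male)
    ages = rng.uniform(age_low, age_high, size=n)
    width = max(3, len(str(n)))
    return [SubjectProfile(f"{id_prefix}-{i + 1:0{width}d}", sexes[i], float(ages[i]))
            for i in range(n)]
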