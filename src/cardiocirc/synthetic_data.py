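"""Synthetic cohorts with known ground truth.

Two kinds of cohort are generated, emulating the statistical structure
of the two data-collection modes the model targets:

* *dense* cohorts: 24 h beat-to-beat RR streams (~1e5 beats/subject)
  built by cumulative-time advance — the next beat occurs one RR
  interval after the current one, with the circadian mean evaluated at
  the running clock time and one AR noise step per beat;
* *sparse* cohorts: ambulatory heart-rate readings on the clinic
  schedule (every 15 min from 08:00 to 22:00, every 30 min from 22:00
  to 08:00 — 56 day + 20 night = 76 ticks per 24 h), with optional
  random missingness thinning the average to a target count.

Default cohort compositions follow the data sets the model was built
for: 18 dense subjects (5 males aged 26-45, 13 females aged 20-50) and
67 sparse subjects (34 males, ages 17-72).  Every generator returns a
:class:`GroundTruthManifest` that exactly reproduces the data when
replayed with the same seed.

The per-beat AR stepping of the dense generator reinterprets the AR
process's time step per beat rather than per minute; this is a fixture
convention (recorded in the manifest), not a physiological claim.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model_core import CircadianCoefficients, DEFAULT_COEFFICIENTS, SubjectProfile
from .preprocessing import AmbulatoryHRSeries, RRSeries
from .rr_simulator import (ARModel, SimulationSpec, default_ar_model,
                           simulate_ar_noise, simulate_subject_rr, _subject_seed)

__all__ = [
    "GroundTruthManifest",
    "make_dense_cohort",
    "make_sparse_cohort",
    "ambulatory_schedule",
    "make_minute_cohort",
]

_MS_PER_HOUR = 3.6e6


@dataclass
class GroundTruthManifest:
    """Generating parameters of a synthetic cohort (replayable per seed)."""

    kind: str
    coefficients: CircadianCoefficients
    ar: ARModel
    n: int
    males: int
    age_ranges: dict
    seed: int
    notes: str = ""

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "coefficients": self.coefficients.to_dict(),
            "ar": self.ar.to_dict(),
            "n": self.n,
            "males": self.males,
            "age_ranges": self.age_ranges,
            "seed": self.seed,
            "notes": self.notes,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _cohort_profiles(n, males, male_age_range, female_age_range, seed, prefix):
    if not 0 <= males <= n:
        raise ValueError("need 0 <= males <= n")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xC0]))
    profiles = []
    width = max(2, len(str(n)))
    for i in range(n):
        sex = 1 if i < males else 0
        lo, hi = male_age_range if sex == 1 else female_age_range
        if lo > hi:
            raise ValueError("invalid age range")
        profiles.append(SubjectProfile(f"{prefix}{i + 1:0{width}d}", sex,
                                       float(rng.uniform(lo, hi))))
    return profiles


def _dense_subject_stream(subject, coeffs, ar, seed, duration_hours):
    """Beat-level (elapsed_hour, rr_ms) arrays by cumulative-time advance."""
    rng = np.random.default_rng(_subject_seed(seed, subject.subject_id))
    # enough AR steps for the shortest plausible beats (RR >= ~350 ms)
    cap = int(duration_hours * _MS_PER_HOUR / 350.0) + 16
    eps = simulate_ar_noise(ar, cap, seed=rng) if ar.tau > 0 or ar.order else np.zeros(cap)
    b = coeffs.as_array()
    const = b[0] + b[1] * subject.sex + b[2] * subject.age + b[3] * subject.age ** 2
    a_sin = b[4] + b[6] * subject.sex
    a_cos = b[5] + b[7] * subject.sex
    omega = 2.0 * math.pi / 24.0
    t_ms = 0.0
    end_ms = duration_hours * _MS_PER_HOUR
    times, rrs = [], []
    i = 0
    while t_ms < end_ms:
        hour = t_ms / _MS_PER_HOUR
        mu = const + a_sin * math.sin(omega * hour) + a_cos * math.cos(omega * hour)
        rr = math.exp(mu + eps[i])
        times.append(hour)
        rrs.append(rr)
        t_ms += rr
        i += 1
        if i >= eps.size:  # pragma: no cover - cap sized for RR >= 350 ms
            raise RuntimeError("AR noise buffer exhausted")
    return np.asarray(times), np.asarray(rrs)


def make_dense_cohort(n: int = 18, males: int = 5,
                      male_age_range=(26.0, 45.0), female_age_range=(20.0, 50.0),
                      seed: int = 0,
                      coefficients: CircadianCoefficients = DEFAULT_COEFFICIENTS,
                      ar: ARModel | None = None,
                      duration_hours: float = 24.0,
                      out_dir=None):
    """Dense beat-level cohort (default: 18 subjects, 5 male, 24 h each).

    Returns ``(series, manifest)`` where ``series`` is a list of
    beat-level :class:`RRSeries` (~1e5 beats each for 24 h).  If
    ``out_dir`` is given, one CSV per subject plus ``manifest.yaml``
    are written there and the file paths are returned instead of the
    in-memory series.  Byte-identical across runs for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ar = default_ar_model() if ar is None else ar
    profiles = _cohort_profiles(n, males, male_age_range, female_age_range,
                                seed, prefix="dense")
    series = []
    for p in profiles:
        t, rr = _dense_subject_stream(p, coefficients, ar, seed, duration_hours)
        series.append(RRSeries(p, np.mod(t, 24.0), rr, elapsed_hours=t))
    manifest = GroundTruthManifest(
        kind="dense", coefficients=coefficients, ar=ar, n=n, males=males,
        age_ranges={"male": list(male_age_range), "female": list(female_age_range)},
        seed=int(seed),
        notes="beat-level cumulative-time advance; one AR step per beat")
    if out_dir is None:
        return series, manifest
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in series:
        df = pd.DataFrame({
            "subject_id": s.subject.subject_id, "sex": s.subject.sex,
            "age": s.subject.age, "hour": s.hours,
            "elapsed_hour": s.elapsed_hours, "rr_ms": s.rr_ms})
        path = out / f"{s.subject.subject_id}.csv"
        df.to_csv(path, index=False, float_format="%.6f")
        paths.append(path)
    manifest.save(out / "manifest.yaml")
    return paths, manifest


def ambulatory_schedule() -> np.ndarray:
    """Elapsed-hour ticks of the ambulatory schedule, starting 08:00.

    Every 15 min from 08:00 to 22:00 (56 ticks) then every 30 min until
    08:00 next morning (20 ticks): 76 readings per 24 h.
    """
    day = 8.0 + 0.25 * np.arange(56)      # 08:00 .. 21:45
    night = 22.0 + 0.5 * np.arange(20)    # 22:00 .. 31:30 (= 07:30)
    return np.concatenate([day, night])


def make_sparse_cohort(n: int = 67, males: int = 34, age_range=(17.0, 72.0),
                       seed: int = 0,
                       coefficients: CircadianCoefficients = DEFAULT_COEFFICIENTS,
                       ar: ARModel | None = None,
                       mean_readings: float | None = 71.0,
                       count_range=(35, 99),
                       out_dir=None):
    """Sparse ambulatory-HR cohort (default: 67 subjects, 34 male).

    RR is simulated on the ambulatory schedule and reported as heart
    rate (HR = 60000 / RR).  When ``mean_readings`` is given, readings
    are dropped independently with probability 1 - mean/76 and the
    per-subject count is constrained to ``count_range`` by redrawing;
    ``mean_readings=None`` keeps all 76 ticks.

    Returns ``(series, manifest)`` (or CSV path + manifest with ``out_dir``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ar = default_ar_model() if ar is None else ar
    profiles = _cohort_profiles(n, males, age_range, age_range, seed, prefix="amb")
    ticks = ambulatory_schedule()
    keep_p = None if mean_readings is None else float(mean_readings) / ticks.size
    if keep_p is not None and not 0 < keep_p <= 1:
        raise ValueError("mean_readings must be in (0, 76]")
    spec = SimulationSpec(coefficients=coefficients, ar=ar, times=ticks, seed=int(seed))
    series = []
    for p in profiles:
        rr = simulate_subject_rr(spec, p)
        keep = np.ones(ticks.size, dtype=bool)
        if keep_p is not None and keep_p < 1:
            miss_rng = np.random.default_rng(
                np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xA5,
                                        zlib.crc32(p.subject_id.encode())]))
            for _ in range(1000):
                keep = miss_rng.random(ticks.size) < keep_p
                if count_range[0] <= keep.sum() <= count_range[1]:
                    break
        hr = 60000.0 / rr.rr_ms[keep]
        series.append(AmbulatoryHRSeries(p, np.mod(ticks[keep], 24.0), hr,
                                         elapsed_hours=ticks[keep]))
    manifest = GroundTruthManifest(
        kind="sparse", coefficients=coefficients, ar=ar, n=n, males=males,
        age_ranges={"all": list(age_range)}, seed=int(seed),
        notes=f"ambulatory schedule, 76 ticks/24 h; mean_readings={mean_readings}")
    if out_dir is None:
        return series, manifest
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = [pd.DataFrame({
        "subject_id": s.subject.subject_id, "sex": s.subject.sex,
        "age": s.subject.age, "hour": s.hours,
        "elapsed_hour": s.elapsed_hours, "hr_bpm": s.hr_bpm}) for s in series]
    path = out / "ambulatory_cohort.csv"
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")
    manifest.save(out / "manifest.yaml")
    return [path], manifest


def make_minute_cohort(n: int = 18, males: int = 5,
                       male_age_range=(26.0, 45.0), female_age_range=(20.0, 50.0),
                       seed: int = 0,
                       coefficients: CircadianCoefficients = DEFAULT_COEFFICIENTS,
                       ar: ARModel | None = None,
                       duration_hours: float = 24.0):
    """Cohort sampled directly on the 1-minute modelling grid.

    A lighter stand-in for ``make_dense_cohort`` + minute resampling:
    RR simulated at 1440 one-minute points per subject per 24 h, the
    representation the regression is actually fitted on.
    """
    from .rr_simulator import uniform_grid

    if n < 1:
        raise ValueError("n must be >= 1")
    ar = default_ar_model() if ar is None else ar
    profiles = _cohort_profiles(n, males, male_age_range, female_age_range,
                                seed, prefix="min")
    spec = SimulationSpec(coefficients=coefficients, ar=ar,
                          times=uniform_grid(0.0, 1.0, duration_hours), seed=int(seed))
    series = [simulate_subject_rr(spec, p) for p in profiles]
    manifest = GroundTruthManifest(
        kind="minute", coefficients=coefficients, ar=ar, n=n, males=males,
        age_ranges={"male": list(male_age_range), "female": list(female_age_range)},
        seed=int(seed), notes="1-minute grid, one AR step per minute")
    return series, manifest
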