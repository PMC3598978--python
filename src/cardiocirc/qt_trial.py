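"""Virtual QT-prolongation trials on top of the circadian RR model.

The building blocks of an in-silico thorough-QT-style study:

* the Hill inhibition factor translating a drug concentration and a
  channel IC50 into a fractional block of that ionic current;
* Fridericia's cube-root heart-rate correction QTcF = QT / (RR/1000)^(1/3);
* a pluggable QT engine (RR + per-channel inhibition -> QT in ms); the
  shipped default is a simple surrogate in which drug-free QTcF is a
  subject constant and IKr block prolongs QT linearly — detailed
  cell-level electrophysiology (e.g. a ventricular-fibre pseudo-ECG
  model) can be plugged in behind the same contract;
* a triplicate trial design (3 studies x 20 subjects by default, six
  clock times, each subject observed drug-free and on-drug);
* the two baseline corrections used to report drug effect: a single
  pooled baseline (dQTcF) and an individualised time-matched baseline
  (dQTcF_i).

The contrast between the two corrections is the scientific point: the
single-point baseline confounds the circadian QTcF drift with the drug
effect, while the individualised correction cancels each subject's own
baseline exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import canonical_hour
from .rr_simulator import (ARModel, SimulationSpec, generate_virtual_cohort,
                           simulate_subject_rr)

__all__ = [
    "DrugChannelSpec",
    "TrialDesign",
    "QTObservation",
    "SurrogateQTEngine",
    "MOXIFLOXACIN_CHANNELS",
    "hill_inhibition_factor",
    "fridericia_qtc",
    "surrogate_qt_engine",
    "run_virtual_trial",
    "observations_to_frame",
    "delta_qtcf_single_baseline",
    "delta_qtcf_individualized",
]


@dataclass(frozen=True)
class DrugChannelSpec:
    """Concentration-response input for one cardiac ion channel.

    ``ic50_um`` is the concentration (uM) giving 50% block, ``hill_n``
    the Hill slope, ``concentration_um`` the free drug concentration.
    """

    channel: str
    ic50_um: float
    hill_n: float = 1.0
    concentration_um: float = 0.0

    def __post_init__(self):
        if not self.ic50_um > 0:
            raise ValueError("ic50_um must be > 0")
        if not self.hill_n > 0:
            raise ValueError("hill_n must be > 0")
        if self.concentration_um < 0:
            raise ValueError("concentration_um must be >= 0")


#: Moxifloxacin channel-block inputs at the free Cmax after a 400 mg
#: oral dose (3.8 uM): IC50s for IKr, INa and ICa.  At this
#: concentration INa/ICa block is negligible; IKr drives the QT effect.
MOXIFLOXACIN_CHANNELS = (
    DrugChannelSpec("IKr", ic50_um=29.0, hill_n=1.0, concentration_um=3.8),
    DrugChannelSpec("INa", ic50_um=127.2, hill_n=1.0, concentration_um=3.8),
    DrugChannelSpec("ICa", ic50_um=168.9, hill_n=1.0, concentration_um=3.8),
)


def hill_inhibition_factor(spec: DrugChannelSpec) -> float:
    """Fractional current block: 1 / (1 + (IC50 / C)^n).

    0 at zero concentration, 0.5 exactly at C = IC50 (any slope),
    strictly increasing in concentration, and < 1 for finite C.
    """
    if spec.concentration_um == 0.0:
        return 0.0
    return 1.0 / (1.0 + (spec.ic50_um / spec.concentration_um) ** spec.hill_n)


def fridericia_qtc(qt_ms, rr_ms):
    """Fridericia-corrected QT: QTcF = QT / (RR/1000)^(1/3), all in ms."""
    qt = np.asarray(qt_ms, dtype=float)
    rr = np.asarray(rr_ms, dtype=float)
    if not (np.all(qt > 0) and np.all(rr > 0)):
        raise ValueError("QT and RR must be > 0")
    out = qt / np.cbrt(rr / 1000.0)
    return float(out) if np.ndim(qt_ms) == 0 and np.ndim(rr_ms) == 0 else out


@dataclass(frozen=True)
class SurrogateQTEngine:
    """Default QT engine: Fridericia-consistent baseline plus an IKr drug term.

    The drug-free QT is ``qtc0_ms * (RR/1000)^(1/3) + offset``, so the
    drug-free, offset-free QTcF equals ``qtc0_ms`` at every RR.
    ``drug_gain_ms`` scales the prolongation per unit IKr inhibition;
    ``subject_sd_ms`` is the SD of the additive per-subject QT offset
    (drawn once per subject per trial by the trial runner, identical in
    the baseline and on-drug arms).

    ``drug_effect`` selects where the drug term enters:

    * ``"qtcf"`` (default) — the effect is heart-rate independent on
      the corrected scale: QTcF rises by exactly ``gain * block`` at
      any RR.  This mirrors how a flat individualised dQTcF_i is read
      in thorough-QT practice.
    * ``"qt"`` — ``gain * block`` is added to the raw QT, so the QTcF
      effect shrinks/grows with RR as ``gain * block / (RR/1000)^(1/3)``.
    """

    qtc0_ms: float = 400.0
    drug_gain_ms: float = 50.0
    subject_sd_ms: float = 10.0
    drug_effect: str = "qtcf"

    def __post_init__(self):
        if not self.qtc0_ms > 0:
            raise ValueError("qtc0_ms must be > 0")
        if self.drug_gain_ms < 0 or self.subject_sd_ms < 0:
            raise ValueError("drug_gain_ms and subject_sd_ms must be >= 0")
        if self.drug_effect not in ("qtcf", "qt"):
            raise ValueError("drug_effect must be 'qtcf' or 'qt'")

    def draw_subject_offset(self, rng: np.random.Generator) -> float:
        return float(rng.normal(0.0, self.subject_sd_ms)) if self.subject_sd_ms else 0.0

    def __call__(self, rr_ms: float, inhibition: dict, subject_offset_ms: float = 0.0) -> float:
        c = float(np.cbrt(rr_ms / 1000.0))
        drug = self.drug_gain_ms * float(inhibition.get("IKr", 0.0))
        if self.drug_effect == "qtcf":
            drug *= c  # adds exactly gain*block to QTcF
        qt = self.qtc0_ms * c + drug + subject_offset_ms
        if qt <= 0:
            raise ValueError("surrogate engine produced non-positive QT")
        return qt


def surrogate_qt_engine(qtc0_ms: float = 400.0, drug_gain_ms: float = 50.0,
                        subject_sd_ms: float = 10.0,
                        drug_effect: str = "qtcf") -> SurrogateQTEngine:
    """Construct the default surrogate QT engine (see :class:`SurrogateQTEngine`)."""
    return SurrogateQTEngine(qtc0_ms, drug_gain_ms, subject_sd_ms, drug_effect)


@dataclass(frozen=True)
class TrialDesign:
    """Triplicate virtual-trial design.

    Defaults: 3 trials of 20 subjects (sex ratio 0.5, ages uniform on
    20-50 y) observed at clock hours 4, 8, 12, 16, 20 and 24 (hour 24
    is evaluated as hour 0 by periodicity), each drug-free and on-drug.
    """

    times_of_day: tuple = (4.0, 8.0, 12.0, 16.0, 20.0, 24.0)
    n_per_trial: int = 20
    n_trials: int = 3
    sex_ratio: float = 0.5
    age_low: float = 20.0
    age_high: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_trial < 1 or self.n_trials < 1:
            raise ValueError("n_per_trial and n_trials must be >= 1")
        if not len(self.times_of_day):
            raise ValueError("times_of_day must be non-empty")


@dataclass(frozen=True)
class QTObservation:
    """One simulated (trial, subject, hour, arm) record with RR, QT and QTcF."""

    trial_id: int
    subject_id: str
    sex: int
    age: float
    hour: float
    rr_ms: float
    qt_ms: float
    qtcf_ms: float
    arm: str  # "baseline" | "drug"

    def __post_init__(self):
        if not (self.rr_ms > 0 and self.qt_ms > 0 and self.qtcf_ms > 0):
            raise ValueError("rr, qt and qtcf must be > 0")
        if self.arm not in ("baseline", "drug"):
            raise ValueError("arm must be 'baseline' or 'drug'")


def run_virtual_trial(design: TrialDesign, engine, drug, model: SimulationSpec
                      ) -> list[QTObservation]:
    """Run the triplicate virtual study.

    For every trial replicate a fresh virtual cohort is generated; each
    subject's RR at the design hours comes from the circadian simulator
    (one draw, shared by both arms — the drug is assumed not to change
    heart rate).  QT is evaluated drug-free (zero concentration) and at
    the specified drug exposure through the Hill inhibition factors;
    QTcF is attached to every record.

    ``drug`` is an iterable of :class:`DrugChannelSpec`; ``model``
    supplies the circadian coefficients, AR process and root seed (the
    design's hours override the spec's time grid; ``design.seed`` is
    combined with ``model.seed`` for cohort/offset draws).
    """
    drug = list(drug)
    inh_drug = {d.channel: hill_inhibition_factor(d) for d in drug}
    inh_zero = {d.channel: 0.0 for d in drug}
    hours = np.asarray(design.times_of_day, dtype=float)
    root = np.random.SeedSequence([int(model.seed) & 0x7FFFFFFF,
                                   int(design.seed) & 0x7FFFFFFF])
    obs: list[QTObservation] = []
    for trial_id, child in enumerate(root.spawn(design.n_trials), start=1):
        cohort_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        offset_rng = np.random.default_rng(child.spawn(1)[0])
        cohort = generate_virtual_cohort(
            design.n_per_trial, design.sex_ratio, design.age_low, design.age_high,
            seed=cohort_seed, id_prefix=f"t{trial_id}")
        spec = SimulationSpec(coefficients=model.coefficients, ar=model.ar,
                              times=canonical_hour(hours), seed=cohort_seed)
        for subject in cohort:
            offset = (engine.draw_subject_offset(offset_rng)
                      if hasattr(engine, "draw_subject_offset") else 0.0)
            rr = simulate_subject_rr(spec, subject).rr_ms
            for h, rr_h in zip(hours, rr):
                for arm, inh in (("baseline", inh_zero), ("drug", inh_drug)):
                    qt = engine(rr_h, inh, offset)
                    obs.append(QTObservation(
                        trial_id, subject.subject_id, subject.sex, subject.age,
                        float(h), float(rr_h), float(qt),
                        fridericia_qtc(qt, rr_h), arm))
    return obs


def observations_to_frame(obs) -> pd.DataFrame:
    """Trial records as a tidy frame (one row per observation)."""
    return pd.DataFrame([o.__dict__ for o in obs])


def _split_arms(obs):
    df = obs if isinstance(obs, pd.DataFrame) else observations_to_frame(obs)
    if df.empty:
        raise ValueError("no observations")
    base = df[df["arm"] == "baseline"]
    drug = df[df["arm"] == "drug"]
    if base.empty:
        raise ValueError("no baseline records: run the trial with a baseline arm")
    if drug.empty:
        raise ValueError("no on-drug records")
    return base, drug


def _summarise(deltas: pd.DataFrame) -> pd.DataFrame:
    g = deltas.groupby("hour")["delta_qtcf_ms"]
    out = pd.DataFrame({"mean_ms": g.mean(), "sd_ms": g.std(ddof=1), "n": g.size()})
    out.index.name = "hour"
    return out


def delta_qtcf_single_baseline(obs) -> pd.DataFrame:
    """dQTcF with a single pooled baseline, summarised per hour.

    The baseline is the mean QTcF over all subjects and all times
    within each trial replicate; dQTcF(subject, hour) is the on-drug
    QTcF minus that pooled mean.  Returns per-hour mean, SD and n.
    """
    base, drug = _split_arms(obs)
    pooled = base.groupby("trial_id")["qtcf_ms"].mean()
    deltas = drug.assign(
        delta_qtcf_ms=drug["qtcf_ms"] - drug["trial_id"].map(pooled).to_numpy())
    return _summarise(deltas)


def delta_qtcf_individualized(obs) -> pd.DataFrame:
    """dQTcF_i with each subject's own time-matched baseline, per hour.

    dQTcF_i(subject, hour) = on-drug QTcF - that subject's drug-free
    QTcF at the same hour (within the same trial).  Unpaired records
    raise, naming the offending (subject, hour).
    """
    base, drug = _split_arms(obs)
    keys = ["trial_id", "subject_id", "hour"]
    merged = drug.merge(base[keys + ["qtcf_ms"]], on=keys, how="left",
                        suffixes=("", "_baseline"), validate="one_to_one")
    missing = merged["qtcf_ms_baseline"].isna()
    if missing.any():
        bad = merged.loc[missing, ["subject_id", "hour"]].head(5).to_records(index=False)
        raise ValueError(f"unpaired on-drug record(s), e.g. {list(bad)}")
    merged = merged.assign(delta_qtcf_ms=merged["qtcf_ms"] - merged["qtcf_ms_baseline"])
    return _summarise(merged)
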