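"""Synthetic trial schedules and questionnaire payloads.

Emulates the data-entry behaviour of participants in a smartphone-based
trial: each participant logs in once (key generation), submits a
questionnaire on a fixed visit schedule, and either completes (revealing
the key) or drops out.  The instrument set mirrors the outcome measures of
a home-exercise trial for breast cancer survivors — physical activity
(GPAQ), fear of recurrence (CARS overall fear index), depression (PHQ-9),
fatigue (CFS), insomnia (AIS), and quality of life (EQ-5D).  Item counts
and response ranges follow the instruments' public definitions; answers are
drawn uniformly within range, since only payload *shape* matters to the
integrity machinery, never questionnaire semantics or treatment effects.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Any

from .canonical import sha256_hex
from .errors import ConfigurationError

ARM_LABELS = ("intervention", "control")


@dataclass(frozen=True)
class InstrumentSpec:
    """One questionnaire: named items with inclusive integer answer ranges."""

    name: str
    items: tuple[tuple[str, int, int], ...]  # (item, low, high)


def _ranged(prefix: str, n: int, low: int, high: int) -> tuple[tuple[str, int, int], ...]:
    return tuple((f"{prefix}{i}", low, high) for i in range(1, n + 1))


#: Public item counts / ranges. GPAQ: 16 items mixing yes-no gates,
#: days-per-week and minutes-per-day quantities; the ranges below keep that
#: shape without scoring semantics.
INSTRUMENTS: dict[str, InstrumentSpec] = {
    "GPAQ": InstrumentSpec("GPAQ", (
        ("p1", 0, 1), ("p2", 0, 7), ("p3", 0, 960),
        ("p4", 0, 1), ("p5", 0, 7), ("p6", 0, 960),
        ("p7", 0, 1), ("p8", 0, 7), ("p9", 0, 960),
        ("p10", 0, 1), ("p11", 0, 7), ("p12", 0, 960),
        ("p13", 0, 1), ("p14", 0, 7), ("p15", 0, 960),
        ("p16", 0, 1440),
    )),
    "CARS": InstrumentSpec("CARS", _ranged("fear", 4, 1, 6)),
    "PHQ-9": InstrumentSpec("PHQ-9", _ranged("q", 9, 0, 3)),
    "CFS": InstrumentSpec("CFS", _ranged("q", 15, 1, 5)),
    "AIS": InstrumentSpec("AIS", _ranged("q", 8, 0, 3)),
    "EQ-5D": InstrumentSpec("EQ-5D", _ranged("dim", 5, 1, 5) + (("vas", 0, 100),)),
}


@dataclass
class TrialConfig:
    """Size, schedule and randomness of one synthetic trial."""

    n_participants: int = 100
    records_per_participant: int = 10
    visit_interval_days: float = 7.0
    dropout_probability: float = 0.05
    arm_labels: tuple[str, str] = ARM_LABELS
    instruments: tuple[str, ...] = tuple(INSTRUMENTS)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be >= 0")
        if self.records_per_participant <= 0:
            raise ConfigurationError("records_per_participant must be positive")
        if self.visit_interval_days <= 0:
            raise ConfigurationError("visit_interval_days must be positive")
        if not 0.0 <= self.dropout_probability <= 1.0:
            raise ConfigurationError("dropout_probability must be in [0, 1]")
        for name in self.instruments:
            if name not in INSTRUMENTS:
                raise ConfigurationError(f"unknown instrument {name!r}")
        if not self.instruments:
            raise ConfigurationError("at least one instrument required")

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "TrialConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        doc = dict(doc)
        for tup in ("arm_labels", "instruments"):
            if tup in doc:
                doc[tup] = tuple(doc[tup])
        try:
            return cls(**doc)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from None


@dataclass(frozen=True)
class ScheduleEvent:
    """One scheduled client action."""

    day: float
    participant_id: str
    account_id: str
    action: str  # "login" | "submit" | "complete"
    visit: int = 0
    instrument: str | None = None
    arm: str | None = None


def derive_seed(master_seed: int, label: str) -> int:
    """Independent per-participant substream seed (< 2^31)."""
    digest = sha256_hex(f"{master_seed}:{label}".encode("utf-8"))
    return int(digest[:8], 16) % (2**31)


def participant_rng(config: TrialConfig, participant_id: str) -> random.Random:
    return random.Random(derive_seed(config.master_seed, participant_id))


def generate_payload(instrument: str, rng: random.Random,
                     arm: str | None = None) -> dict[str, Any]:
    """Draw one questionnaire payload with every answer within range."""
    try:
        spec = INSTRUMENTS[instrument]
    except KeyError:
        raise ConfigurationError(f"unknown instrument {instrument!r}") from None
    payload: dict[str, Any] = {
        "instrument": spec.name,
        "answers": {item: rng.randint(low, high) for item, low, high in spec.items},
    }
    if arm is not None:
        payload["arm"] = arm
    return payload


def generate_trial(config: TrialConfig) -> list[ScheduleEvent]:
    """Deterministic event schedule for one synthetic trial.

    Each participant gets an independent random substream derived from the
    master seed, so removing one participant never perturbs another's
    schedule or answers.  A non-dropout produces 1 login + R submissions +
    1 completion; a dropout stops after a random number of submissions and
    never reveals the key.
    """
    events: list[ScheduleEvent] = []
    for i in range(config.n_participants):
        pid = f"P{i + 1:04d}"
        account = f"acct-{pid}"
        rng = participant_rng(config, pid)
        arm = rng.choice(list(config.arm_labels))
        # staggered enrollment within the first visit interval
        login_day = rng.uniform(0.0, config.visit_interval_days)
        drops_out = rng.random() < config.dropout_probability
        n_records = config.records_per_participant
        if drops_out:
            n_records = rng.randint(0, config.records_per_participant - 1)
        events.append(ScheduleEvent(login_day, pid, account, "login", arm=arm))
        for v in range(1, n_records + 1):
            day = login_day + v * config.visit_interval_days
            instrument = config.instruments[(v - 1) % len(config.instruments)]
            events.append(ScheduleEvent(day, pid, account, "submit",
                                        visit=v, instrument=instrument, arm=arm))
        if not drops_out:
            day = login_day + (n_records + 1) * config.visit_interval_days
            events.append(ScheduleEvent(day, pid, account, "complete",
                                        visit=n_records + 1, arm=arm))
    events.sort(key=lambda e: (e.day, e.participant_id, e.visit))
    return events


def schedule_horizon(events: list[ScheduleEvent]) -> int:
    """Whole simulated days needed to play out the schedule."""
    if not events:
        return 1
    return int(max(e.day for e in events)) + 2
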