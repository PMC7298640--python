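"""Discrete-time orchestration of a full simulated trial.

Plays a synthetic event schedule through the whole pipeline — client
devices, relay layer, ledger — one simulated day at a time.  Each day:
scheduled client actions run, clients flush their outbound queues to two
randomly selected relays, relays dispatch to the ledger, pending
transactions are cut into blocks and committed on every healthy peer, and
the periodic health check restores failed peers.  Scenario hooks (attack
and fault scripts) observe and perturb the run at day boundaries, which
keeps runs replayable: the same seed and scenario always produce a
byte-identical ledger.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Any, Optional

from .canonical import SimClock
from .client import AccountDirectory, ClientDevice, first_login
from .ledger import Ledger
from .relay import RelayLayer, RetentionPolicy
from .synthetic import (
    ScheduleEvent,
    TrialConfig,
    derive_seed,
    generate_payload,
    generate_trial,
    schedule_horizon,
)


class Scenario:
    """Base class for attack / fault scripts; hooks are no-ops by default."""

    #: extra simulated days appended after the schedule (for recovery/drain)
    extra_days: int = 0

    def on_day_start(self, day: int, ctx: "RunContext") -> None:  # pragma: no cover
        pass

    def on_day_end(self, day: int, ctx: "RunContext") -> None:  # pragma: no cover
        pass

    def summary(self) -> dict[str, Any]:
        return {}


@dataclass
class RunContext:
    config: TrialConfig
    seed: int
    clock: SimClock
    accounts: AccountDirectory
    clients: dict[str, ClientDevice]
    relays: RelayLayer
    ledger: Ledger
    schedule: list[ScheduleEvent]
    app_auth_token: str
    log: list[str] = field(default_factory=list)

    def rng(self, label: str) -> random.Random:
        """A reproducible substream tied to this run's seed."""
        return random.Random(derive_seed(self.seed, label))


@dataclass
class RunResult:
    ctx: RunContext
    manifest: dict[str, Any]

    @property
    def ledger(self) -> Ledger:
        return self.ctx.ledger


def run_trial(
    config: TrialConfig,
    seed: int,
    scenario: Optional[Scenario] = None,
    retention_days: int = 7,
) -> RunResult:
    """Simulate one trial to quiescence and return ledger plus manifest."""
    config = replace(config, master_seed=seed)
    schedule = generate_trial(config)
    clock = SimClock(0.0)
    app_token = f"app-{derive_seed(seed, 'app-token'):08x}"
    participant_ids = sorted({e.participant_id for e in schedule})

    accounts = AccountDirectory()
    for pid in participant_ids:
        accounts.issue(f"acct-{pid}", pid, app_token)

    relays = RelayLayer([app_token], participant_ids,
                        RetentionPolicy(retention_days))
    ledger = Ledger([app_token], participant_ids)
    ctx = RunContext(config, seed, clock, accounts, {}, relays, ledger,
                     schedule, app_token)

    key_rngs = {pid: ctx.rng(f"key:{pid}") for pid in participant_ids}
    relay_rngs = {pid: ctx.rng(f"relay:{pid}") for pid in participant_ids}
    payload_rngs = {pid: ctx.rng(f"payload:{pid}") for pid in participant_ids}

    events_by_day: dict[int, list[ScheduleEvent]] = {}
    for e in schedule:
        events_by_day.setdefault(int(e.day), []).append(e)

    horizon = schedule_horizon(schedule) + (scenario.extra_days if scenario else 0)

    for day in range(horizon):
        if scenario:
            scenario.on_day_start(day, ctx)
        for event in events_by_day.get(day, ()):
            clock.day = event.day
            pid = event.participant_id
            if event.action == "login":
                device, _ = first_login(accounts.lookup(event.account_id),
                                        key_rngs[pid], clock)
                ctx.clients[pid] = device
            elif event.action == "submit":
                payload = generate_payload(event.instrument, payload_rngs[pid],
                                           arm=event.arm)
                ctx.clients[pid].create_clinical_record(payload, clock)
            elif event.action == "complete":
                ctx.clients[pid].complete_trial(clock)
        # evening batch: flush clients, forward relays, commit, health check
        clock.day = day + 0.9
        for pid in sorted(ctx.clients):
            ctx.clients[pid].flush_outbound(relays, relay_rngs[pid], clock)
        relays.dispatch_all(ledger, clock)
        ledger.cut_all()
        for line in ledger.health_check_tick(clock):
            ctx.log.append(line)
        if scenario:
            scenario.on_day_end(day, ctx)

    ledger.cut_all()
    manifest = build_manifest(ctx)
    if scenario:
        manifest["scenario"] = scenario.summary()
    return RunResult(ctx, manifest)


def build_manifest(ctx: RunContext) -> dict[str, Any]:
    relays = ctx.relays.relays
    per_relay = {
        rid: {
            "enqueued": r.n_enqueued,
            "committed": r.n_committed,
            "expired": r.n_expired,
            "rejected": r.n_rejected,
            "retained": len(r.queue),
        }
        for rid, r in sorted(relays.items())
    }
    records_created = sum(c.next_seq for c in ctx.clients.values())
    return {
        "seed": ctx.seed,
        "config": {
            "n_participants": ctx.config.n_participants,
            "records_per_participant": ctx.config.records_per_participant,
            "visit_interval_days": ctx.config.visit_interval_days,
            "dropout_probability": ctx.config.dropout_probability,
            "instruments": list(ctx.config.instruments),
            "retention_days": ctx.relays.retention.retention_days,
        },
        "counters": {
            "participants": len(ctx.clients),
            "records_created": records_created,
            "client_retained": sum(len(c.outbound_queue)
                                   for c in ctx.clients.values()),
            "ledger_committed": ctx.ledger.committed_count(),
            "ledger_blocks": len(ctx.ledger.reference_chain()),
            "error_records": ctx.ledger.error_records,
            "relays": per_relay,
        },
    }
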