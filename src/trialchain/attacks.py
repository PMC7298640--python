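"""Scripted adversary and fault scenarios, plus randomized detection sweeps.

The attacker model: the adversary observes every transported byte (all
envelopes, registered hashes, the app's authentication token) but never an
unrevealed secret key, and cannot break SHA-256.  Scenarios act at day
boundaries of a replayable run, so a given seed and scenario always
reproduce the same ledger.

Implemented scenarios:

* impersonation — the attacker submits clinical records for a genuine
  participant from another device, with a fabricated (or replayed) chain
  hash, delivered through two relays like any honest record;
* relay injection — one compromised relay alters a forwarded record or
  injects a fabricated one toward the ledger;
* node failure / org failure — validating peers fail mid-run and the
  health check restores them from a healthy replica;
* total outage with retention — every peer is down for a stretch and the
  relay queues carry the trial across the gap;
* ledger tamper — a single byte of a committed transaction is changed in a
  copied export (post-hoc falsification of an audit copy).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Any, Optional

from . import canonical, verification
from .client import RecordEnvelope, RecordKind
from .engine import RunContext, RunResult, Scenario, run_trial
from .relay import RelayQueueItem
from .synthetic import INSTRUMENTS, TrialConfig, generate_payload

#: Trial size used by the randomized sweeps: large enough to give every
#: scenario genuine records to target, small enough to repeat hundreds of
#: times.
SWEEP_CONFIG = TrialConfig(n_participants=5, records_per_participant=5,
                           dropout_probability=0.0)


def _fabricated_payload(rng: random.Random) -> dict[str, Any]:
    instrument = rng.choice(sorted(INSTRUMENTS))
    return generate_payload(instrument, rng)


# ---------------------------------------------------------------------------
# impersonation (stolen account / brute force)
# ---------------------------------------------------------------------------


class ImpersonationAttack(Scenario):
    """Inject attacker-crafted clinical records for a genuine participant.

    The attacker holds the app token and a stolen session but not the
    secret key, so the injected record's hash is either fabricated with the
    attacker's own key or replayed from an observed genuine record.  Either
    way recomputation with the true (later revealed) key mismatches.
    """

    def __init__(self, seed: int, target: Optional[str] = None,
                 mode: str = "fabricated") -> None:
        if mode not in ("fabricated", "replayed"):
            raise ValueError(f"unknown impersonation mode {mode!r}")
        self.rng = random.Random(seed)
        self.target = target
        self.mode = mode
        self.injected: Optional[dict[str, Any]] = None

    def on_day_end(self, day: int, ctx: RunContext) -> None:
        if self.injected is not None:
            return
        if self.target is None:
            candidates = sorted(pid for pid, c in ctx.clients.items()
                                if c.next_seq >= 3 and not c.completed)
            if not candidates:
                return
            self.target = self.rng.choice(candidates)
        device = ctx.clients.get(self.target)
        if device is None or device.next_seq < 3 or device.completed:
            return
        seq = self.rng.randint(1, device.next_seq - 1)  # existing clinical seq
        payload = _fabricated_payload(self.rng)
        ts = ctx.clock.timestamp()
        doc = {"participant_id": self.target, "kind": "CLINICAL_DATA",
               "seq": seq, "timestamp": ts, "payload": payload}
        if self.mode == "replayed":
            # reuse a hash the attacker observed on the wire
            observed = [t.envelope.client_hash
                        for t in ctx.ledger.query_participant(self.target)
                        if t.envelope.client_hash is not None]
            fake_hash = self.rng.choice(observed) if observed else "f" * 64
        else:
            attacker_key = canonical.new_secret_key(self.rng)
            fake_hash = canonical.chain_hash(
                canonical.canonical_encode(doc), "", attacker_key)
        env = RecordEnvelope(self.target, RecordKind.CLINICAL_DATA, seq, ts,
                             payload, fake_hash, ctx.app_auth_token)
        pair = ctx.relays.select_relays(self.rng)
        for rid in pair:
            ctx.relays.relay(rid).authenticate(env, ctx.clock)
        self.injected = {"target": self.target, "seq": seq,
                         "mode": self.mode, "relays": list(pair)}

    def summary(self) -> dict[str, Any]:
        return {"kind": "IMPERSONATION", "injected": self.injected}


# ---------------------------------------------------------------------------
# relay compromise
# ---------------------------------------------------------------------------


class RelayInjectionAttack(Scenario):
    """A fraudulently accessed relay falsifies data toward the ledger.

    ``alter`` mode rewrites one answer of a forwarded record (hash left as
    observed); ``fabricate`` mode emits a wholly attacker-made record from
    the compromised relay alone.
    """

    def __init__(self, seed: int, relay_id: str = "R1",
                 mode: str = "alter") -> None:
        if mode not in ("alter", "fabricate"):
            raise ValueError(f"unknown relay-injection mode {mode!r}")
        self.rng = random.Random(seed)
        self.relay_id = relay_id
        self.mode = mode
        self.result: Optional[dict[str, Any]] = None

    def on_day_start(self, day: int, ctx: RunContext) -> None:
        relay = ctx.relays.relay(self.relay_id)
        if not relay.compromised and self.mode == "alter":
            relay.compromised = True
            relay.tamper = self._alter_once
        self._ctx = ctx

    def _alter_once(self, env: RecordEnvelope) -> RecordEnvelope:
        if self.result is not None or env.kind is not RecordKind.CLINICAL_DATA:
            return env
        payload = {k: (dict(v) if isinstance(v, dict) else v)
                   for k, v in env.payload.items()}
        answers = payload.get("answers")
        if not isinstance(answers, dict) or not answers:
            return env
        item = self.rng.choice(sorted(answers))
        answers[item] = int(answers[item]) + 1
        altered = RecordEnvelope(env.participant_id, env.kind, env.seq,
                                 env.timestamp, payload, env.client_hash,
                                 env.app_auth_token)
        self.result = {"target": env.participant_id, "seq": env.seq,
                       "item": item, "relay": self.relay_id, "mode": self.mode}
        return altered

    def on_day_end(self, day: int, ctx: RunContext) -> None:
        if self.mode != "fabricate" or self.result is not None:
            return
        committed = [t for t in ctx.ledger.committed_transactions()
                     if t.envelope.kind is RecordKind.CLINICAL_DATA]
        if not committed:
            return
        victim = self.rng.choice(committed).envelope
        payload = _fabricated_payload(self.rng)
        ts = ctx.clock.timestamp()
        doc = {"participant_id": victim.participant_id, "kind": "CLINICAL_DATA",
               "seq": victim.seq, "timestamp": ts, "payload": payload}
        fake_hash = canonical.chain_hash(
            canonical.canonical_encode(doc), "",
            canonical.new_secret_key(self.rng))
        env = RecordEnvelope(victim.participant_id, RecordKind.CLINICAL_DATA,
                             victim.seq, ts, payload, fake_hash,
                             ctx.app_auth_token)
        relay = ctx.relays.relay(self.relay_id)
        relay.compromised = True
        relay.queue.append(RelayQueueItem(env, self.relay_id, ctx.clock.day))
        relay.n_enqueued += 1
        self.result = {"target": victim.participant_id, "seq": victim.seq,
                       "relay": self.relay_id, "mode": self.mode}

    def summary(self) -> dict[str, Any]:
        return {"kind": "RELAY_INJECTION", "injected": self.result}


# ---------------------------------------------------------------------------
# peer failure and outages
# ---------------------------------------------------------------------------


class NodeFailureScenario(Scenario):
    """Fail one or more validating peers; the health check restores them."""

    extra_days = 3  # let recovery and re-sync settle

    def __init__(self, peer_ids: list[str], onset_day: int,
                 duration_days: int = 1) -> None:
        self.peer_ids = list(peer_ids)
        self.onset_day = onset_day
        self.duration_days = duration_days

    def on_day_start(self, day: int, ctx: RunContext) -> None:
        if self.onset_day <= day < self.onset_day + self.duration_days:
            for pid in self.peer_ids:
                ctx.ledger.fail_peer(pid)

    def summary(self) -> dict[str, Any]:
        return {"kind": "NODE_FAILURE", "peers": self.peer_ids,
                "onset_day": self.onset_day, "duration_days": self.duration_days}


class LedgerOutageScenario(Scenario):
    """All six peers down for a stretch; relay queues bridge the gap.

    The health check cannot re-sync with no healthy source, so recovery at
    the end of the outage models the operator restoring the network within
    the retention window.
    """

    def __init__(self, onset_day: int, duration_days: int) -> None:
        self.onset_day = onset_day
        self.duration_days = duration_days
        self.extra_days = duration_days + 3

    def on_day_start(self, day: int, ctx: RunContext) -> None:
        if self.onset_day <= day < self.onset_day + self.duration_days:
            for pid in sorted(ctx.ledger.peers):
                ctx.ledger.fail_peer(pid)
        elif day == self.onset_day + self.duration_days:
            ctx.ledger.revive_all()

    def summary(self) -> dict[str, Any]:
        return {"kind": "LEDGER_OUTAGE", "onset_day": self.onset_day,
                "duration_days": self.duration_days}


class RelayOutageScenario(Scenario):
    """All relay servers unreachable for a stretch; the client-side queues
    retain every record until the relays come back."""

    def __init__(self, onset_day: int, duration_days: int) -> None:
        self.onset_day = onset_day
        self.duration_days = duration_days
        self.extra_days = duration_days + 3

    def on_day_start(self, day: int, ctx: RunContext) -> None:
        down = self.onset_day <= day < self.onset_day + self.duration_days
        for rid in sorted(ctx.relays.relays):
            ctx.relays.relay(rid).reachable = not down

    def summary(self) -> dict[str, Any]:
        return {"kind": "RELAY_OUTAGE", "onset_day": self.onset_day,
                "duration_days": self.duration_days}


# ---------------------------------------------------------------------------
# post-hoc tampering of an exported audit copy
# ---------------------------------------------------------------------------


def _leaf_paths(doc: Any, prefix: tuple) -> list[tuple]:
    if isinstance(doc, dict):
        paths = []
        for k in sorted(doc):
            paths.extend(_leaf_paths(doc[k], prefix + (k,)))
        return paths
    if isinstance(doc, list):
        paths = []
        for i, v in enumerate(doc):
            paths.extend(_leaf_paths(v, prefix + (i,)))
        return paths
    return [prefix]


def tamper_sites(lines: list[str]) -> list[tuple[int, tuple]]:
    """Enumerate every tamperable scalar of every committed transaction:
    payload leaves plus the client hash and timestamp of each envelope."""
    sites: list[tuple[int, tuple]] = []
    for i, line in enumerate(lines):
        doc = canonical.canonical_decode(line.encode("utf-8"))
        env = doc["envelope"]
        for path in _leaf_paths(env["payload"], ("envelope", "payload")):
            sites.append((i, path))
        if "client_hash" in env:
            sites.append((i, ("envelope", "client_hash")))
        sites.append((i, ("envelope", "timestamp")))
    return sites


def _mutate_scalar(value: Any, rng: random.Random) -> Any:
    if isinstance(value, bool):
        return not value
    if isinstance(value, int):
        return value + 1
    if isinstance(value, float):
        return value + 1.0
    if isinstance(value, str) and value:
        i = rng.randrange(len(value))
        repl = "x" if value[i] != "x" else "y"
        return value[:i] + repl + value[i + 1:]
    return "tampered"


def ledger_tamper_attack(lines: list[str], position: int,
                         rng: random.Random) -> tuple[list[str], Optional[dict]]:
    """Change one byte of one committed transaction in a copied export.

    ``position`` indexes the enumeration of tamperable scalars; a position
    beyond the data is a no-op (export returned unchanged).  The line stays
    parseable, so detection is verification's job, not the JSON parser's.
    """
    sites = tamper_sites(lines)
    if position >= len(sites) or position < 0:
        return list(lines), None
    line_idx, path = sites[position]
    doc = canonical.canonical_decode(lines[line_idx].encode("utf-8"))
    node = doc
    for key in path[:-1]:
        node = node[key]
    old = node[path[-1]]
    node[path[-1]] = _mutate_scalar(old, rng)
    out = list(lines)
    out[line_idx] = canonical.canonical_encode(doc).decode("utf-8")
    return out, {"line": line_idx, "path": list(map(str, path)), "old": old,
                 "new": node[path[-1]]}


def tamper_block_hash(manifest: dict[str, Any], block_index: int) -> dict[str, Any]:
    """Flip one hex character inside a stored block hash (audit-copy attack)."""
    out = {"blocks": [dict(b) for b in manifest["blocks"]]}
    h = out["blocks"][block_index]["block_hash"]
    flipped = ("0" if h[0] != "0" else "1") + h[1:]
    out["blocks"][block_index]["block_hash"] = flipped
    return out


# ---------------------------------------------------------------------------
# randomized detection sweeps
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    n_runs: int
    n_detected: int
    details: list[dict[str, Any]] = field(default_factory=list)

    @property
    def detection_rate(self) -> float:
        return self.n_detected / self.n_runs if self.n_runs else float("nan")


def impersonation_sweep(n_runs: int, seed: int,
                        config: TrialConfig = SWEEP_CONFIG) -> SweepResult:
    """Randomized impersonation attacks; detected = verification fails for
    the impersonated participant."""
    detected = 0
    details = []
    for i in range(n_runs):
        mode = "fabricated" if i % 2 == 0 else "replayed"
        scenario = ImpersonationAttack(seed=seed * 100003 + i, mode=mode)
        result = run_trial(config, seed=seed * 20011 + i, scenario=scenario)
        report = verification.verify_trial(result.ledger)
        inj = scenario.injected
        hit = (inj is not None and not report.overall_pass
               and inj["target"] in report.failing_participants())
        detected += hit
        details.append({"run": i, "mode": mode, "injected": inj,
                        "detected": hit,
                        "condition": report.first_failing_condition()})
    return SweepResult(n_runs, detected, details)


def relay_injection_sweep(n_runs: int, seed: int,
                          config: TrialConfig = SWEEP_CONFIG) -> SweepResult:
    detected = 0
    details = []
    for i in range(n_runs):
        mode = "alter" if i % 2 == 0 else "fabricate"
        relay_id = f"R{i % 3 + 1}"
        scenario = RelayInjectionAttack(seed=seed * 100019 + i,
                                        relay_id=relay_id, mode=mode)
        result = run_trial(config, seed=seed * 20021 + i, scenario=scenario)
        report = verification.verify_trial(result.ledger)
        inj = scenario.result
        hit = (inj is not None and not report.overall_pass
               and inj["target"] in report.failing_participants())
        detected += hit
        details.append({"run": i, "mode": mode, "injected": inj,
                        "detected": hit,
                        "condition": report.first_failing_condition()})
    return SweepResult(n_runs, detected, details)


def ledger_tamper_sweep(n_positions: int, seed: int,
                        config: TrialConfig = SWEEP_CONFIG) -> SweepResult:
    """Random single-byte tampers of one honest export; each must fail
    verification of the tampered copy."""
    from .ledger import export_manifest, export_transaction_lines, rebuild_chain

    result = run_trial(config, seed=seed)
    chain = result.ledger.reference_chain()
    lines = export_transaction_lines(chain)
    manifest = export_manifest(chain)
    sites = tamper_sites(lines)
    rng = random.Random(seed * 7919 + 13)
    detected = 0
    details = []
    for i in range(n_positions):
        pos = rng.randrange(len(sites))
        tampered, what = ledger_tamper_attack(lines, pos, rng)
        report = verification.verify_chain(rebuild_chain(tampered, manifest))
        hit = not report.overall_pass
        detected += hit
        details.append({"run": i, "site": what, "detected": hit})
    return SweepResult(n_positions, detected, details)


def honest_sweep(n_seeds: int, seed: int,
                 config: TrialConfig = SWEEP_CONFIG) -> SweepResult:
    """False-positive check: honest runs across seeds must all verify."""
    false_positives = 0
    details = []
    for i in range(n_seeds):
        result = run_trial(config, seed=seed * 30011 + i)
        report = verification.verify_trial(result.ledger)
        fp = not report.overall_pass
        false_positives += fp
        details.append({"run": i, "false_positive": fp})
    return SweepResult(n_seeds, false_positives, details)


def node_failure_counters(result: RunResult) -> dict[str, int]:
    """Loss/error bookkeeping for a fault run: registrations that never
    committed, endorsement errors, and peer-chain divergence."""
    ledger = result.ledger
    counters = result.manifest["counters"]
    expected = 2 * counters["records_created"]
    committed = counters["ledger_committed"]
    chains = [tuple(b.block_hash for b in p.chain)
              for p in ledger.peers.values()]
    return {
        "lost_registrations": expected - committed
        - sum(r["retained"] + r["expired"]
              for r in counters["relays"].values())
        - 2 * counters["client_retained"],
        "error_records": counters["error_records"],
        "expired": sum(r["expired"] for r in counters["relays"].values()),
        "peers_identical": int(len(set(chains)) == 1),
    }
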