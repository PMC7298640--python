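"""Relay servers between client devices and the ledger.

Three authenticated, append-only relays each hold a retention-bounded
inbound queue (modelled on a cloud message queue with 7-day retention).  A
client sends every record to two of the three relays, chosen uniformly at
random; the relay forwards queued records to the ledger byte-identically,
retaining them while the ledger is unavailable and discarding them only
once they exceed the retention period.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Iterable, Optional

from .canonical import SimClock
from .client import RecordEnvelope
from .errors import ConfigurationError

if TYPE_CHECKING:  # pragma: no cover
    from .ledger import Ledger

RELAY_IDS = ("R1", "R2", "R3")


@dataclass
class RetentionPolicy:
    """Maximum age (days) a queued, undelivered record may reach."""

    retention_days: int = 7

    def __post_init__(self) -> None:
        if self.retention_days <= 0:
            raise ConfigurationError("retention_days must be positive")


@dataclass
class RelayQueueItem:
    envelope: RecordEnvelope
    relay_id: str
    enqueued_at: float  # simulated day


@dataclass
class RelayServer:
    relay_id: str
    accepted_app_tokens: set[str]
    known_accounts: set[str]
    queue: list[RelayQueueItem] = field(default_factory=list)
    compromised: bool = False
    reachable: bool = True
    #: attack hook: maps an envelope to the (possibly altered) envelope the
    #: compromised relay actually forwards; identity when honest.
    tamper: Optional[Callable[[RecordEnvelope], RecordEnvelope]] = None
    #: lifetime counters (committed + retained-now + expired == enqueued)
    n_enqueued: int = 0
    n_committed: int = 0
    n_expired: int = 0
    n_rejected: int = 0

    def can_accept(self, envelope: RecordEnvelope) -> bool:
        """Side-effect-free authentication check (token + known account)."""
        return (
            self.reachable
            and envelope.app_auth_token in self.accepted_app_tokens
            and envelope.participant_id in self.known_accounts
        )

    def authenticate(self, envelope: RecordEnvelope, clock: SimClock) -> bool:
        """Authenticate and, on success, enqueue the envelope."""
        if not self.can_accept(envelope):
            return False
        self.queue.append(RelayQueueItem(envelope, self.relay_id, clock.day))
        self.n_enqueued += 1
        return True

    def dispatch(
        self, ledger: "Ledger", clock: SimClock, policy: RetentionPolicy
    ) -> dict[str, int]:
        """Forward queued items to the ledger in order.

        Items whose age has reached the retention period are dropped and
        counted as expired; items the ledger cannot take (unavailability)
        are retained for the next dispatch.
        """
        from .ledger import RegisterStatus  # local import: avoids cycle

        counts = {"committed": 0, "retained": 0, "expired": 0}
        remaining: list[RelayQueueItem] = []
        for item in self.queue:
            if clock.day - item.enqueued_at >= policy.retention_days:
                counts["expired"] += 1
                self.n_expired += 1
                continue
            env = item.envelope
            if self.compromised and self.tamper is not None:
                env = self.tamper(env)
            status = ledger.register(env, self.relay_id, clock)
            if status in (RegisterStatus.COMMITTED, RegisterStatus.DUPLICATE):
                counts["committed"] += 1
                self.n_committed += 1
            elif status is RegisterStatus.UNAVAILABLE:
                counts["retained"] += 1
                remaining.append(item)
            else:  # REJECTED: endorsement refused; relay drops, client unaware
                self.n_rejected += 1
        self.queue = remaining
        return counts


class RelayLayer:
    """The trial's fixed set of three relay servers plus retention policy."""

    def __init__(
        self,
        accepted_app_tokens: Iterable[str],
        known_accounts: Iterable[str],
        retention: RetentionPolicy | None = None,
        relay_ids: Iterable[str] = RELAY_IDS,
    ) -> None:
        tokens = set(accepted_app_tokens)
        accounts = set(known_accounts)
        self.retention = retention or RetentionPolicy()
        self.relays: dict[str, RelayServer] = {
            rid: RelayServer(rid, tokens, accounts) for rid in relay_ids
        }

    def relay(self, relay_id: str) -> RelayServer:
        return self.relays[relay_id]

    def select_relays(self, rng: random.Random) -> tuple[str, str]:
        """Draw one of the three unordered relay pairs uniformly at random.

        Selection belongs to the app ("the app randomly selects two relay
        servers"), but lives here so audit tooling can re-derive admissible
        pairs from the same configuration.
        """
        ids = sorted(self.relays)
        if len(ids) < 2:
            raise ConfigurationError("relay selection needs at least 2 relays")
        pair = rng.sample(ids, 2)
        return tuple(sorted(pair))  # type: ignore[return-value]

    def dispatch_all(self, ledger: "Ledger", clock: SimClock) -> dict[str, int]:
        totals = {"committed": 0, "retained": 0, "expired": 0}
        for rid in sorted(self.relays):
            counts = self.relays[rid].dispatch(ledger, clock, self.retention)
            for k in totals:
                totals[k] += counts[k]
        return totals

    def queued_total(self) -> int:
        return sum(len(r.queue) for r in self.relays.values())
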