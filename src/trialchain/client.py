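"""Simulated participant smartphone.

Models the client-side life cycle: the account is locked at first login
(impersonation guard), a per-participant secret key is generated and kept on
the device, every record is chained to its predecessor with the keyed
SHA-256 chain hash, and the key itself is revealed in a final record when
the participant completes the trial.  Outbound records sit in a retry queue
until two relay servers have both accepted them.
"""

from __future__ import annotations

import enum
import random
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Any, Mapping

from . import canonical
from .errors import (
    AccountLockedError,
    EmptyPayloadError,
    TrialCompletedError,
    UnknownAccountError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .relay import RelayLayer


class RecordKind(str, enum.Enum):
    """The three record types a client produces during a trial."""

    KEY_GENERATED = "KEY_GENERATED"
    CLINICAL_DATA = "CLINICAL_DATA"
    KEY_REVEAL = "KEY_REVEAL"


@dataclass(frozen=True)
class RecordEnvelope:
    """One client-generated record as transported and committed.

    ``client_hash`` is the chain hash over the record's canonical document
    (answers plus embedded metadata); it is ``None`` only for KEY_REVEAL,
    which terminates verification instead of extending the chain and carries
    the secret key in its payload.
    """

    participant_id: str
    kind: RecordKind
    seq: int
    timestamp: str
    payload: dict[str, Any]
    client_hash: str | None
    app_auth_token: str

    def hashed_document(self) -> dict[str, Any]:
        """The document the chain hash covers: payload plus metadata.

        Embedding participant id, kind, sequence number and timestamp means
        tampering with metadata is as detectable as tampering with answers.
        """
        return {
            "participant_id": self.participant_id,
            "kind": self.kind.value,
            "seq": self.seq,
            "timestamp": self.timestamp,
            "payload": self.payload,
        }

    def to_dict(self) -> dict[str, Any]:
        doc = {
            "participant_id": self.participant_id,
            "kind": self.kind.value,
            "seq": self.seq,
            "timestamp": self.timestamp,
            "payload": self.payload,
            "app_auth_token": self.app_auth_token,
        }
        if self.client_hash is not None:
            doc["client_hash"] = self.client_hash
        return doc

    def to_bytes(self) -> bytes:
        """Canonical transport bytes; byte equality defines record identity."""
        return canonical.canonical_encode(self.to_dict())

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "RecordEnvelope":
        return cls(
            participant_id=doc["participant_id"],
            kind=RecordKind(doc["kind"]),
            seq=int(doc["seq"]),
            timestamp=doc["timestamp"],
            payload=dict(doc["payload"]),
            client_hash=doc.get("client_hash"),
            app_auth_token=doc["app_auth_token"],
        )


@dataclass
class Account:
    """A login account issued by the trial site."""

    account_id: str
    participant_id: str
    app_auth_token: str
    locked: bool = False


class AccountDirectory:
    """The set of accounts issued for the trial."""

    def __init__(self) -> None:
        self._accounts: dict[str, Account] = {}

    def issue(self, account_id: str, participant_id: str, app_auth_token: str) -> Account:
        acct = Account(account_id, participant_id, app_auth_token)
        self._accounts[account_id] = acct
        return acct

    def lookup(self, account_id: str) -> Account:
        try:
            return self._accounts[account_id]
        except KeyError:
            raise UnknownAccountError(f"unknown account {account_id!r}") from None

    def __iter__(self):
        return iter(self._accounts.values())


@dataclass
class ClientDevice:
    """Client state: secret key, chain tip, sequence counter, retry queue."""

    participant_id: str
    account: Account
    secret_key: str
    app_auth_token: str
    locked: bool = True
    last_hash: str = ""
    next_seq: int = 0
    outbound_queue: list[RecordEnvelope] = field(default_factory=list)
    completed: bool = False

    # -- record creation ---------------------------------------------------

    def _chained_envelope(
        self, kind: RecordKind, payload: dict[str, Any], clock: canonical.SimClock
    ) -> RecordEnvelope:
        seq = self.next_seq
        ts = clock.timestamp()
        doc = {
            "participant_id": self.participant_id,
            "kind": kind.value,
            "seq": seq,
            "timestamp": ts,
            "payload": payload,
        }
        h = canonical.chain_hash(
            canonical.canonical_encode(doc), self.last_hash, self.secret_key
        )
        env = RecordEnvelope(
            participant_id=self.participant_id,
            kind=kind,
            seq=seq,
            timestamp=ts,
            payload=payload,
            client_hash=h,
            app_auth_token=self.app_auth_token,
        )
        self.last_hash = h
        self.next_seq = seq + 1
        self.outbound_queue.append(env)
        return env

    def create_clinical_record(
        self, answers: Mapping[str, Any], clock: canonical.SimClock
    ) -> RecordEnvelope:
        """Chain and enqueue one questionnaire record."""
        if self.completed:
            raise TrialCompletedError(f"{self.participant_id} already completed")
        if not answers:
            raise EmptyPayloadError("clinical record with no answers")
        return self._chained_envelope(RecordKind.CLINICAL_DATA, dict(answers), clock)

    def complete_trial(self, clock: canonical.SimClock) -> RecordEnvelope:
        """Reveal the secret key; no further records can be created."""
        if self.completed:
            raise TrialCompletedError(f"{self.participant_id} already completed")
        seq = self.next_seq
        ts = clock.timestamp()
        env = RecordEnvelope(
            participant_id=self.participant_id,
            kind=RecordKind.KEY_REVEAL,
            seq=seq,
            timestamp=ts,
            payload={"secret_key": self.secret_key},
            client_hash=None,
            app_auth_token=self.app_auth_token,
        )
        self.next_seq = seq + 1
        self.completed = True
        self.outbound_queue.append(env)
        return env

    # -- delivery ----------------------------------------------------------

    def flush_outbound(
        self, relays: "RelayLayer", rng: random.Random, clock: canonical.SimClock
    ) -> dict[str, int]:
        """Attempt delivery of every queued envelope to two relays.

        An envelope is dequeued only when both relays of a freshly selected
        pair accept it; the acceptance is atomic per attempt, so a record
        never ends up with copies on more than two relays.  On the first
        failure the flush stops, preserving queue (and therefore chain)
        order; the next flush draws a fresh pair.
        """
        delivered = 0
        while self.outbound_queue:
            env = self.outbound_queue[0]
            pair = relays.select_relays(rng)
            servers = [relays.relay(rid) for rid in pair]
            if all(s.can_accept(env) for s in servers):
                for s in servers:
                    s.authenticate(env, clock)
                self.outbound_queue.pop(0)
                delivered += 1
            else:
                break
        return {"delivered": delivered, "retained": len(self.outbound_queue)}


def first_login(
    account: Account, rng: random.Random, clock: canonical.SimClock
) -> tuple[ClientDevice, RecordEnvelope]:
    """First login: lock the account, generate the secret key, emit record 0.

    The lock is irreversible — a second login attempt (an impersonation
    attempt with a stolen account) raises :class:`AccountLockedError`.
    """
    if account.locked:
        raise AccountLockedError(f"account {account.account_id!r} is locked")
    account.locked = True
    device = ClientDevice(
        participant_id=account.participant_id,
        account=account,
        secret_key=canonical.new_secret_key(rng),
        app_auth_token=account.app_auth_token,
    )
    env = device._chained_envelope(
        RecordKind.KEY_GENERATED, {"event": "secret key generated"}, clock
    )
    return device, env
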