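"""The predetermined validation and verification protocol.

After participants complete data entry, every record on the ledger is
checked against three conditions, per participant:

C1 (completeness)  — the ledger holds all required record types: exactly
    one key-generation record (seq 0), exactly one key-reveal record, and a
    gap-free run of clinical records between them.
C2 (hashchain)     — with the revealed secret key, every registered client
    hash is reproduced by recomputing the chain over the committed records
    (sorted by generation time, ties broken by sequence number).  Only the
    true participant's device held the key, so a record forged without it
    cannot carry a hash that recomputes.
C3 (relay copies)  — every record arrived as exactly two byte-identical
    copies from two distinct relay servers, which rules out records
    injected or altered by a single compromised relay.

On top of the per-participant conditions, block linkage of the ledger copy
itself is verified by recomputing every block hash.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Optional

from . import canonical
from .client import RecordEnvelope, RecordKind
from .errors import KeyUnavailable
from .ledger import Block, Ledger, Transaction, verify_block_linkage

CHAINED_KINDS = (RecordKind.KEY_GENERATED, RecordKind.CLINICAL_DATA)


@dataclass
class ConditionResult:
    condition: str  # "C1" | "C2" | "C3"
    passed: bool
    failures: list[tuple[int, str]] = field(default_factory=list)
    evaluable: bool = True

    def to_dict(self) -> dict[str, Any]:
        return {
            "condition": self.condition,
            "passed": self.passed,
            "evaluable": self.evaluable,
            "failures": [{"seq": s, "reason": r} for s, r in self.failures],
        }


def _result(condition: str, failures: list[tuple[int, str]],
            evaluable: bool = True) -> ConditionResult:
    return ConditionResult(condition, evaluable and not failures,
                           failures, evaluable)


@dataclass
class ParticipantResult:
    participant_id: str
    completed: bool
    c1: ConditionResult
    c2: ConditionResult
    c3: ConditionResult
    n_transactions: int

    @property
    def passed(self) -> bool:
        return self.c1.passed and self.c2.passed and self.c3.passed

    def failing_conditions(self) -> list[str]:
        return [c.condition for c in (self.c1, self.c2, self.c3) if not c.passed]

    def to_dict(self) -> dict[str, Any]:
        return {
            "participant_id": self.participant_id,
            "completed": self.completed,
            "passed": self.passed,
            "n_transactions": self.n_transactions,
            "conditions": [self.c1.to_dict(), self.c2.to_dict(), self.c3.to_dict()],
        }


@dataclass
class ValidationReport:
    participants: dict[str, ParticipantResult]
    linkage_ok: bool
    first_broken_block: Optional[int]
    n_transactions: int

    @property
    def unverifiable(self) -> list[str]:
        """Participants without a key reveal (dropouts): C2 not evaluable."""
        return sorted(p for p, r in self.participants.items() if not r.completed)

    @property
    def overall_pass(self) -> bool:
        """Linkage holds and every completed participant passes C1-C3."""
        return self.linkage_ok and all(
            r.passed for r in self.participants.values() if r.completed)

    def failing_participants(self) -> list[str]:
        return sorted(p for p, r in self.participants.items()
                      if r.completed and not r.passed)

    def first_failing_condition(self) -> Optional[str]:
        """Lowest-numbered condition that failed for any completed
        participant (reported, not assumed, when several mechanisms fire)."""
        for cond in ("C1", "C2", "C3"):
            for r in self.participants.values():
                if r.completed and cond in r.failing_conditions():
                    return cond
        return None

    def to_dict(self) -> dict[str, Any]:
        return {
            "overall_pass": self.overall_pass,
            "linkage_ok": self.linkage_ok,
            "first_broken_block": self.first_broken_block,
            "n_transactions": self.n_transactions,
            "n_participants": len(self.participants),
            "unverifiable": self.unverifiable,
            "failing_participants": self.failing_participants(),
            "first_failing_condition": self.first_failing_condition(),
            "participants": [r.to_dict()
                             for _, r in sorted(self.participants.items())],
        }

    def to_table(self) -> str:
        rows = [f"{'participant':<12} {'complete':<9} {'C1':<5} {'C2':<5} "
                f"{'C3':<5} {'records':>7}"]
        for pid, r in sorted(self.participants.items()):
            def mark(c: ConditionResult) -> str:
                return "n/a" if not c.evaluable else ("pass" if c.passed else "FAIL")
            rows.append(f"{pid:<12} {str(r.completed):<9} {mark(r.c1):<5} "
                        f"{mark(r.c2):<5} {mark(r.c3):<5} {r.n_transactions:>7}")
        rows.append(f"linkage: {'ok' if self.linkage_ok else 'BROKEN at block %s' % self.first_broken_block}")
        rows.append(f"overall: {'PASS' if self.overall_pass else 'FAIL'}")
        return "\n".join(rows)


# -- helpers ---------------------------------------------------------------


def _distinct_records(records: Iterable[Transaction]) -> dict[int, list[RecordEnvelope]]:
    """Group committed transactions by seq, deduplicating the relay copies:
    one entry per distinct envelope byte string at each seq."""
    by_seq: dict[int, dict[bytes, RecordEnvelope]] = {}
    for tx in records:
        env = tx.envelope
        by_seq.setdefault(env.seq, {}).setdefault(env.to_bytes(), env)
    return {seq: list(envs.values()) for seq, envs in sorted(by_seq.items())}


def extract_revealed_key(records: Iterable[Transaction]) -> Optional[str]:
    for tx in records:
        if tx.envelope.kind is RecordKind.KEY_REVEAL:
            key = tx.envelope.payload.get("secret_key")
            if isinstance(key, str) and canonical.is_hex_digest(key):
                return key
    return None


# -- the three conditions --------------------------------------------------


def check_completeness(records: list[Transaction]) -> ConditionResult:
    """C1: all required record types present, clinical seqs gap-free."""
    failures: list[tuple[int, str]] = []
    distinct = _distinct_records(records)
    gen_seqs = sorted(s for s, envs in distinct.items()
                      if any(e.kind is RecordKind.KEY_GENERATED for e in envs))
    reveal_seqs = sorted(s for s, envs in distinct.items()
                         if any(e.kind is RecordKind.KEY_REVEAL for e in envs))
    clinical_seqs = sorted(s for s, envs in distinct.items()
                           if any(e.kind is RecordKind.CLINICAL_DATA for e in envs))

    if gen_seqs != [0]:
        failures.append((0, "key generation record missing or misplaced"))
    if not reveal_seqs:
        failures.append((0, "key not revealed"))
    elif len(reveal_seqs) > 1:
        failures.append((reveal_seqs[1], "multiple key reveals"))
    if reveal_seqs:
        expected = list(range(1, reveal_seqs[0]))
        for s in expected:
            if s not in clinical_seqs:
                failures.append((s, f"gap at {s}"))
        for s in clinical_seqs:
            if s not in expected:
                failures.append((s, f"unexpected clinical record at {s}"))
    return _result("C1", failures)


def check_hashchain(records: list[Transaction],
                    revealed_key: Optional[str] = None) -> ConditionResult:
    """C2: every registered client hash recomputes from the revealed key.

    Records are taken in generation order (timestamp, then seq as the
    tie-break).  For each distinct committed record at seq *s*, the hash is
    recomputed from its canonical document, the secret key, and each
    registered hash at the preceding chained seq (the empty string at seq
    0); a record passes if any candidate matches.  Trying every candidate
    predecessor localizes a fork: a forged duplicate fails while the
    genuine copy at the same seq still verifies.
    """
    key = revealed_key if revealed_key is not None else extract_revealed_key(records)
    if key is None:
        raise KeyUnavailable("no key reveal among the records")

    chained = [tx for tx in records if tx.envelope.kind in CHAINED_KINDS]
    chained.sort(key=lambda t: (t.envelope.timestamp, t.envelope.seq))
    distinct = _distinct_records(chained)
    failures: list[tuple[int, str]] = []
    seqs = sorted(distinct)
    for i, seq in enumerate(seqs):
        if i == 0:
            prev_candidates = {""}
        else:
            prev_candidates = {e.client_hash for e in distinct[seqs[i - 1]]
                               if e.client_hash is not None}
        valid_prev = [p for p in prev_candidates
                      if p == "" or canonical.is_hex_digest(p)]
        for env in distinct[seq]:
            if env.client_hash is None:
                failures.append((seq, "chained record without a hash"))
                continue
            if not canonical.is_hex_digest(env.client_hash):
                failures.append((seq, "registered hash malformed"))
                continue
            doc_bytes = canonical.canonical_encode(env.hashed_document())
            if not any(canonical.chain_hash(doc_bytes, prev, key) == env.client_hash
                       for prev in valid_prev):
                failures.append((seq, "registered hash does not recompute"))
    return _result("C2", failures)


def check_relay_duplication(records: list[Transaction]) -> ConditionResult:
    """C3: exactly two byte-identical copies from distinct relays per record."""
    failures: list[tuple[int, str]] = []
    by_seq: dict[int, list[Transaction]] = {}
    for tx in records:
        by_seq.setdefault(tx.envelope.seq, []).append(tx)
    for seq in sorted(by_seq):
        group = by_seq[seq]
        if len(group) != 2:
            failures.append((seq, f"{len(group)} copies at seq {seq}"))
            continue
        if group[0].relay_id == group[1].relay_id:
            failures.append((seq, f"duplicate relay at seq {seq}"))
        if group[0].envelope.to_bytes() != group[1].envelope.to_bytes():
            failures.append((seq, f"copies differ at seq {seq}"))
    return _result("C3", failures)


# -- trial-level verification ---------------------------------------------


def verify_participant(participant_id: str,
                       records: list[Transaction]) -> ParticipantResult:
    c1 = check_completeness(records)
    c3 = check_relay_duplication(records)
    key = extract_revealed_key(records)
    completed = key is not None
    if completed:
        c2 = check_hashchain(records, key)
    else:
        # no key: the chain cannot be recomputed — reported, not failed
        c2 = ConditionResult("C2", passed=False, evaluable=False,
                             failures=[(0, "not evaluable: key not revealed")])
    return ParticipantResult(participant_id, completed, c1, c2, c3, len(records))


def verify_chain(chain: list[Block]) -> ValidationReport:
    """Run linkage plus C1-C3 for every participant found on the chain."""
    linkage_ok, broken = verify_block_linkage(chain)
    by_participant: dict[str, list[Transaction]] = {}
    n_tx = 0
    for block in chain:
        for tx in block.tx_list:
            n_tx += 1
            by_participant.setdefault(tx.envelope.participant_id, []).append(tx)
    participants = {pid: verify_participant(pid, txs)
                    for pid, txs in sorted(by_participant.items())}
    return ValidationReport(participants, linkage_ok, broken, n_tx)


def verify_trial(ledger: Ledger) -> ValidationReport:
    """Verify a quiescent ledger (read-only) against the full protocol."""
    return verify_chain(ledger.reference_chain())
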