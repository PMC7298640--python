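"""Simulated permissioned ledger.

Mirrors the deployment the trial ran on: three organizations, each with two
validating peers, spread over independent availability zones.  Transactions
go through the permissioned-blockchain lifecycle — proposal, endorsement by
each organization, policy check at submission, chronological ordering,
block cutting, broadcast, and commit on every healthy peer.  Each peer
holds the full hash-linked chain, so the ledger survives peer failures and
a periodic health check restores failed peers from a healthy replica.

Consensus internals (Raft/BFT, certificate authorities, chaincode VMs) are
not modelled; the simulation keeps the externally observable contract:
total order, replication, endorsement policy, and fault recovery.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, Optional

from . import canonical
from .canonical import GENESIS_HASH, SEP, SimClock, sha256_hex
from .client import RecordEnvelope, RecordKind
from .errors import OrgUnavailable, PolicyNotMet

ORG_IDS = ("Org1", "Org2", "Org3")


class RegisterStatus(enum.Enum):
    COMMITTED = "committed"      # endorsed, ordered, will appear in a block
    DUPLICATE = "duplicate"      # tx_id already known; idempotent success
    REJECTED = "rejected"        # endorsement refused on the merits
    UNAVAILABLE = "unavailable"  # too few healthy orgs; sender should retry


@dataclass
class Transaction:
    """One endorsed ledger entry: an envelope as delivered by one relay.

    The transaction id hashes the envelope bytes together with the relay id,
    so the two intended relay copies of a record are distinct transactions
    and the duplicate check does not suppress the second copy.
    """

    tx_id: str
    envelope: RecordEnvelope
    relay_id: str
    received_at: str
    endorsements: set[str] = field(default_factory=set)

    @classmethod
    def create(
        cls, envelope: RecordEnvelope, relay_id: str, received_at: str
    ) -> "Transaction":
        tx_id = sha256_hex(envelope.to_bytes() + SEP + relay_id.encode("ascii"))
        return cls(tx_id=tx_id, envelope=envelope, relay_id=relay_id,
                   received_at=received_at)

    def to_dict(self) -> dict[str, Any]:
        return {
            "tx_id": self.tx_id,
            "relay_id": self.relay_id,
            "received_at": self.received_at,
            "envelope": self.envelope.to_dict(),
        }

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "Transaction":
        return cls(
            tx_id=doc["tx_id"],
            envelope=RecordEnvelope.from_dict(doc["envelope"]),
            relay_id=doc["relay_id"],
            received_at=doc["received_at"],
        )


@dataclass
class Block:
    index: int
    prev_block_hash: str
    tx_list: list[Transaction]
    block_hash: str

    @staticmethod
    def compute_hash(index: int, prev_block_hash: str,
                     tx_dicts: list[dict[str, Any]]) -> str:
        doc = {"index": index, "prev_block_hash": prev_block_hash,
               "transactions": tx_dicts}
        return sha256_hex(canonical.canonical_encode(doc))

    @classmethod
    def build(cls, index: int, prev_block_hash: str,
              tx_list: list[Transaction]) -> "Block":
        h = cls.compute_hash(index, prev_block_hash,
                             [t.to_dict() for t in tx_list])
        return cls(index, prev_block_hash, list(tx_list), h)


@dataclass
class Peer:
    peer_id: str
    org_id: str
    chain: list[Block] = field(default_factory=list)
    healthy: bool = True

    def tip_hash(self) -> str:
        return self.chain[-1].block_hash if self.chain else GENESIS_HASH

    def append(self, block: Block) -> bool:
        """Validate linkage and content hash, then append. Rejects malformed."""
        if block.index != len(self.chain):
            return False
        if block.prev_block_hash != self.tip_hash():
            return False
        recomputed = Block.compute_hash(
            block.index, block.prev_block_hash,
            [t.to_dict() for t in block.tx_list])
        if recomputed != block.block_hash:
            return False
        self.chain.append(block)
        return True


def verify_block_linkage(chain: list[Block]) -> tuple[bool, Optional[int]]:
    """Check every block's stored hash and prev link.

    Returns ``(True, None)`` for an intact (possibly empty) chain, else
    ``(False, index_of_first_broken_block)``.
    """
    prev = GENESIS_HASH
    for i, block in enumerate(chain):
        if block.index != i or block.prev_block_hash != prev:
            return False, i
        recomputed = Block.compute_hash(
            block.index, block.prev_block_hash,
            [t.to_dict() for t in block.tx_list])
        if recomputed != block.block_hash:
            return False, i
        prev = block.block_hash
    return True, None


class Ledger:
    """3 orgs x 2 validating peers, 2-of-3 endorsement, batch ordering."""

    def __init__(
        self,
        accepted_app_tokens: Iterable[str],
        known_participants: Iterable[str],
        min_orgs: int = 2,
        batch_size: int = 10,
        org_ids: Iterable[str] = ORG_IDS,
        peers_per_org: int = 2,
    ) -> None:
        self.accepted_app_tokens = set(accepted_app_tokens)
        self.known_participants = set(known_participants)
        org_ids = tuple(org_ids)
        if not 1 <= min_orgs <= len(org_ids):
            raise ValueError("min_orgs must be between 1 and the number of orgs")
        self.min_orgs = min_orgs
        self.batch_size = batch_size
        self.peers: dict[str, Peer] = {}
        self.orgs: dict[str, list[str]] = {}
        for org in org_ids:
            self.orgs[org] = []
            for i in range(peers_per_org):
                pid = f"{org}-peer{i}"
                self.peers[pid] = Peer(pid, org)
                self.orgs[org].append(pid)
        self.pending: list[Transaction] = []
        self.blocks: list[Block] = []  # the ordering service's record
        self._known_txids: set[str] = set()
        self.error_records = 0  # endorsement refusals of delivered envelopes

    # -- health ------------------------------------------------------------

    def healthy_peers(self) -> list[Peer]:
        return [p for p in self.peers.values() if p.healthy]

    def healthy_orgs(self) -> list[str]:
        return [org for org, pids in self.orgs.items()
                if any(self.peers[p].healthy for p in pids)]

    def available(self) -> bool:
        return len(self.healthy_orgs()) >= self.min_orgs

    def fail_peer(self, peer_id: str) -> None:
        self.peers[peer_id].healthy = False

    def health_check_tick(self, clock: SimClock) -> list[str]:
        """Replace each failed peer with a fresh one synced from a healthy peer."""
        events: list[str] = []
        for pid in sorted(self.peers):
            peer = self.peers[pid]
            if peer.healthy:
                continue
            sources = [p for p in self.healthy_peers()]
            if not sources:
                continue  # total outage: auto-scaling has no sync source
            source = sources[0]
            peer.chain = list(source.chain)
            peer.healthy = True
            events.append(f"{clock.timestamp()} {pid} replaced, "
                          f"synced {len(peer.chain)} blocks from {source.peer_id}")
        return events

    def revive_all(self) -> None:
        """Operator recovery after a total outage: restore every peer from
        the ordering service's surviving block record."""
        for peer in self.peers.values():
            peer.chain = list(self.blocks)
            peer.healthy = True

    # -- transaction lifecycle --------------------------------------------

    def endorse(self, org: str, tx: Transaction,
                op: str = "append") -> tuple[bool, Optional[str]]:
        """One organization's endorsement decision.

        The four checks: (1) well-formed proposal, (2) not already
        submitted, (3) valid credential, (4) the operation is an authorized
        append (the chaincode is append-only: no update, no delete).
        """
        if not any(self.peers[p].healthy for p in self.orgs[org]):
            raise OrgUnavailable(f"no healthy peer in {org}")
        reason = self._well_formed(tx.envelope)
        if reason is not None:
            return False, reason
        if tx.tx_id in self._known_txids:
            return False, "already submitted"
        if tx.envelope.app_auth_token not in self.accepted_app_tokens:
            return False, "invalid credential"
        if op != "append":
            return False, "not authorized"
        return True, None

    @staticmethod
    def _well_formed(env: RecordEnvelope) -> Optional[str]:
        if not env.participant_id or not isinstance(env.seq, int) or env.seq < 0:
            return "malformed proposal"
        if env.kind is RecordKind.KEY_REVEAL:
            if env.client_hash is not None:
                return "malformed proposal"
            if not canonical.is_hex_digest(env.payload.get("secret_key", "")):
                return "malformed proposal"
        else:
            if env.client_hash is None or not canonical.is_hex_digest(env.client_hash):
                return "malformed proposal"
        try:
            env.to_bytes()
        except Exception:
            return "malformed proposal"
        return None

    def submit(self, tx: Transaction) -> None:
        """Policy check, then hand to the ordering service."""
        if len(tx.endorsements) < self.min_orgs:
            raise PolicyNotMet(
                f"{len(tx.endorsements)} endorsement(s), need {self.min_orgs}")
        self.pending.append(tx)
        self._known_txids.add(tx.tx_id)
        if len(self.pending) >= self.batch_size:
            self.cut_block()

    def register(self, envelope: RecordEnvelope, relay_id: str,
                 clock: SimClock, op: str = "append") -> RegisterStatus:
        """Full lifecycle for one delivered envelope: propose, endorse, submit."""
        if not self.available():
            return RegisterStatus.UNAVAILABLE
        tx = Transaction.create(envelope, relay_id, clock.timestamp())
        if tx.tx_id in self._known_txids:
            return RegisterStatus.DUPLICATE
        refusals = 0
        for org in sorted(self.orgs):
            try:
                ok, _reason = self.endorse(org, tx, op)
            except OrgUnavailable:
                continue
            if ok:
                tx.endorsements.add(org)
            else:
                refusals += 1
        try:
            self.submit(tx)
        except PolicyNotMet:
            if refusals:
                self.error_records += 1
                return RegisterStatus.REJECTED
            return RegisterStatus.UNAVAILABLE
        return RegisterStatus.COMMITTED

    # -- ordering and commit ----------------------------------------------

    def cut_block(self) -> Optional[Block]:
        """Order pending transactions chronologically (ties by tx_id) and
        commit one block of at most ``batch_size`` of them to every healthy
        peer. Unhealthy peers skip the block and re-sync on recovery."""
        if not self.pending:
            return None
        self.pending.sort(key=lambda t: (t.received_at, t.tx_id))
        batch, self.pending = self.pending[: self.batch_size], self.pending[self.batch_size:]
        prev = self.blocks[-1].block_hash if self.blocks else GENESIS_HASH
        block = Block.build(len(self.blocks), prev, batch)
        self.blocks.append(block)
        self.broadcast_and_commit(block)
        return block

    def broadcast_and_commit(self, block: Block) -> dict[str, bool]:
        results = {}
        for pid in sorted(self.peers):
            peer = self.peers[pid]
            results[pid] = peer.append(block) if peer.healthy else False
        return results

    def cut_all(self) -> int:
        n = 0
        while self.pending:
            self.cut_block()
            n += 1
        return n

    # -- read path ---------------------------------------------------------

    def reference_chain(self) -> list[Block]:
        for pid in sorted(self.peers):
            if self.peers[pid].healthy:
                return self.peers[pid].chain
        return self.blocks  # total outage: fall back to the orderer's record

    def committed_transactions(self) -> Iterator[Transaction]:
        for block in self.reference_chain():
            yield from block.tx_list

    def query_participant(self, participant_id: str) -> list[Transaction]:
        """All committed transactions of one participant, in chain order."""
        return [t for t in self.committed_transactions()
                if t.envelope.participant_id == participant_id]

    def committed_count(self) -> int:
        return sum(len(b.tx_list) for b in self.reference_chain())


# -- export / audit-copy I/O ----------------------------------------------


def export_transaction_lines(chain: list[Block]) -> list[str]:
    """One committed transaction per line, canonical field order (JSON Lines)."""
    lines = []
    for block in chain:
        for tx in block.tx_list:
            doc = {"block_index": block.index, **tx.to_dict()}
            lines.append(canonical.canonical_encode(doc).decode("utf-8"))
    return lines


def export_manifest(chain: list[Block]) -> dict[str, Any]:
    return {
        "blocks": [
            {
                "index": b.index,
                "prev_block_hash": b.prev_block_hash,
                "block_hash": b.block_hash,
                "tx_ids": [t.tx_id for t in b.tx_list],
            }
            for b in chain
        ]
    }


def rebuild_chain(lines: Iterable[str], manifest: dict[str, Any]) -> list[Block]:
    """Reconstruct the block chain from an exported audit copy.

    Stored hashes are taken from the manifest verbatim; linkage verification
    recomputes them, so any byte changed in either file is detected.
    """
    by_block: dict[int, list[Transaction]] = {}
    for line in lines:
        line = line.strip()
        if not line:
            continue
        doc = canonical.canonical_decode(line.encode("utf-8"))
        idx = int(doc.pop("block_index"))
        by_block.setdefault(idx, []).append(Transaction.from_dict(doc))
    chain = []
    for meta in manifest["blocks"]:
        txs = by_block.get(meta["index"], [])
        chain.append(Block(int(meta["index"]), meta["prev_block_hash"],
                           txs, meta["block_hash"]))
    return chain
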