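"""Ledger: endorsement, ordering, block commit, replication and recovery."""

import pytest

from trialchain import Ledger, SimClock, verify_block_linkage
from trialchain.client import RecordEnvelope, RecordKind
from trialchain.errors import OrgUnavailable, PolicyNotMet
from trialchain.ledger import (
    Block,
    RegisterStatus,
    Transaction,
    export_manifest,
    export_transaction_lines,
    rebuild_chain,
)


def make_envelope(pid="P1", seq=0, kind=RecordKind.KEY_GENERATED,
                  token="tok", payload=None):
    if kind is RecordKind.KEY_REVEAL:
        body, h = {"secret_key": "ab" * 32}, None
    else:
        body, h = payload or {"a": seq}, "1" * 64
    return RecordEnvelope(pid, kind, seq, "2019-05-01T00:00:00.000Z",
                          body, h, token)


@pytest.fixture
def ledger():
    return Ledger(["tok"], ["P1", "P2"], batch_size=3)


def register(ledger, env, relay="R1", day=0.0):
    return ledger.register(env, relay, SimClock(day))


# -- endorsement -----------------------------------------------------------

def test_well_formed_transaction_endorsed_by_all_orgs(ledger):
    tx = Transaction.create(make_envelope(), "R1", "t0")
    for org in ledger.orgs:
        assert ledger.endorse(org, tx) == (True, None)


def test_replayed_tx_id_rejected(ledger):
    env = make_envelope()
    assert register(ledger, env) is RegisterStatus.COMMITTED
    tx = Transaction.create(env, "R1", "t0")
    ok, reason = ledger.endorse("Org1", tx)
    assert not ok and reason == "already submitted"
    assert register(ledger, env) is RegisterStatus.DUPLICATE


def test_two_relay_copies_are_distinct_transactions(ledger):
    env = make_envelope()
    assert register(ledger, env, relay="R1") is RegisterStatus.COMMITTED
    assert register(ledger, env, relay="R2") is RegisterStatus.COMMITTED


def test_update_operation_not_authorized(ledger):
    register(ledger, make_envelope())
    tx = Transaction.create(make_envelope(payload={"a": 999}), "R1", "t1")
    ok, reason = ledger.endorse("Org1", tx, op="update")
    assert not ok and reason == "not authorized"


def test_bad_token_refused(ledger):
    assert register(ledger, make_envelope(token="stolen")) is RegisterStatus.REJECTED
    assert ledger.error_records == 1


def test_org_with_no_healthy_peer_cannot_endorse(ledger):
    for pid in ledger.orgs["Org2"]:
        ledger.fail_peer(pid)
    tx = Transaction.create(make_envelope(), "R1", "t0")
    with pytest.raises(OrgUnavailable):
        ledger.endorse("Org2", tx)


# -- policy and ordering ---------------------------------------------------

def test_submit_policy_threshold(ledger):
    tx = Transaction.create(make_envelope(), "R1", "t0")
    tx.endorsements = {"Org1", "Org2", "Org3"}
    ledger.submit(tx)  # 3 of 3 against policy 2: accepted
    tx2 = Transaction.create(make_envelope(seq=1), "R1", "t1")
    tx2.endorsements = {"Org1"}
    with pytest.raises(PolicyNotMet):
        ledger.submit(tx2)


def test_identical_received_at_ordered_by_tx_id(ledger):
    e1 = make_envelope(pid="P1", seq=0)
    e2 = make_envelope(pid="P2", seq=0)
    register(ledger, e1, day=0.0)
    register(ledger, e2, day=0.0)
    ledger.cut_all()
    txs = list(ledger.committed_transactions())
    assert [t.tx_id for t in txs] == sorted(t.tx_id for t in txs)


# -- commit, replication, recovery ----------------------------------------

def test_commit_replicates_to_all_healthy_peers(ledger):
    register(ledger, make_envelope())
    ledger.cut_all()
    tips = {p.tip_hash() for p in ledger.peers.values()}
    assert len(tips) == 1 and len(ledger.peers) == 6


def test_failed_peer_skips_then_resyncs(ledger):
    ledger.fail_peer("Org3-peer1")
    register(ledger, make_envelope())
    ledger.cut_all()
    assert len(ledger.peers["Org3-peer1"].chain) == 0
    ledger.health_check_tick(SimClock(1.0))
    chains = {tuple(b.block_hash for b in p.chain) for p in ledger.peers.values()}
    assert len(chains) == 1
    assert all(p.healthy for p in ledger.peers.values())


def test_whole_org_down_commits_continue(ledger):
    for pid in ledger.orgs["Org1"]:
        ledger.fail_peer(pid)
    assert register(ledger, make_envelope()) is RegisterStatus.COMMITTED
    ledger.cut_all()
    assert ledger.committed_count() == 1


def test_all_orgs_down_is_unavailable(ledger):
    for pid in ledger.peers:
        ledger.fail_peer(pid)
    assert register(ledger, make_envelope()) is RegisterStatus.UNAVAILABLE


def test_block_with_corrupted_prev_rejected_everywhere(ledger):
    register(ledger, make_envelope())
    ledger.cut_all()
    tx = Transaction.create(make_envelope(pid="P2"), "R1", "t1")
    bad = Block.build(1, "f" * 64, [tx])  # wrong prev linkage
    results = ledger.broadcast_and_commit(bad)
    assert not any(results.values())


def test_batching_cuts_blocks_of_at_most_batch_size(ledger):
    for seq in range(7):
        register(ledger, make_envelope(seq=seq, kind=RecordKind.CLINICAL_DATA),
                 day=seq)
    ledger.cut_all()
    sizes = [len(b.tx_list) for b in ledger.reference_chain()]
    assert sum(sizes) == 7 and max(sizes) <= 3


# -- queries ---------------------------------------------------------------

def test_query_unknown_participant_empty(ledger):
    assert ledger.query_participant("P404") == []


def test_query_identical_from_any_healthy_peer(ledger):
    register(ledger, make_envelope(), relay="R1")
    register(ledger, make_envelope(), relay="R2")
    ledger.cut_all()
    assert len(ledger.query_participant("P1")) == 2
    baseline = [t.tx_id for t in ledger.query_participant("P1")]
    # knock out peers one at a time; the query never changes
    for pid in list(ledger.peers):
        ledger.fail_peer(pid)
        if any(p.healthy for p in ledger.peers.values()):
            assert [t.tx_id for t in ledger.query_participant("P1")] == baseline
        ledger.peers[pid].healthy = True


# -- linkage and export ----------------------------------------------------

def test_linkage_untampered_and_empty_chain(ledger):
    assert verify_block_linkage([]) == (True, None)
    register(ledger, make_envelope())
    ledger.cut_all()
    assert verify_block_linkage(ledger.reference_chain()) == (True, None)


def test_linkage_detects_flipped_payload_byte(ledger):
    for seq in range(4):
        register(ledger, make_envelope(seq=seq, kind=RecordKind.CLINICAL_DATA),
                 day=seq)
    ledger.cut_all()
    chain = ledger.reference_chain()
    k = len(chain) - 1
    victim = chain[k].tx_list[0].envelope
    object.__setattr__(victim, "payload", {"a": -1})
    ok, broken = verify_block_linkage(chain)
    assert not ok and broken == k


def test_export_roundtrip_preserves_linkage(ledger):
    for seq in range(5):
        register(ledger, make_envelope(seq=seq, kind=RecordKind.CLINICAL_DATA),
                 day=seq)
    ledger.cut_all()
    chain = ledger.reference_chain()
    lines = export_transaction_lines(chain)
    rebuilt = rebuild_chain(lines, export_manifest(chain))
    assert verify_block_linkage(rebuilt) == (True, None)
    assert export_transaction_lines(rebuilt) == lines
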