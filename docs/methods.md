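# Methods

`trialchain` is a desk-scale simulation of a tamper-evident data-capture
pipeline for decentralized clinical trials that collect electronic
patient-reported outcomes (ePRO) on smartphones.  The system it models
couples three mechanisms: a **client hashchain** keyed by a secret held only
on the participant's device, **redundant delivery** through two of three
relay servers, and a **permissioned ledger** (three organizations, two
validating peers each) that commits hash-linked blocks.  After the trial, a
three-condition protocol verifies the committed data without any manual
source-data verification.

## The client hashchain

At first login the participant's account is locked (an impersonation guard)
and the app draws a 256-bit secret key *s*, kept on the device until trial
completion.  Every record *i* carries a chain hash

```
h_0 = SHA-256(d_0 ‖ 0x1F ‖ "" ‖ 0x1F ‖ s)
h_i = SHA-256(d_i ‖ 0x1F ‖ h_{i-1} ‖ 0x1F ‖ s)
```

where `d_i` is the canonical encoding of the record.  The key-generation
record is the first link of the chain (seq 0); the final key-reveal record
carries *s* itself and no hash — it terminates verification rather than
extending the chain.  Because only the genuine device holds *s* before the
reveal, nobody else can produce a hash that recomputes, and because each
hash folds in its predecessor, any later alteration breaks every subsequent
link.

Two byte-level choices had to be fixed for hashes to be well defined:

* **Canonical JSON.**  UTF-8, sorted keys, minimal separators, no
  NaN/Infinity, shortest round-trip float rendering.  Equal payloads (up to
  field order) hash identically; the encoding is idempotent through
  parse/re-encode.
* **Preimage layout.**  `payload ‖ 0x1F ‖ prev ‖ 0x1F ‖ key`, with `prev`
  empty for the first record.  The non-printable separator (never produced
  by JSON encoding) makes the three-field concatenation collision-free.

`d_i` covers not just the questionnaire answers but the embedded metadata
(participant id, record kind, sequence number, timestamp), so metadata
tampering is as detectable as answer tampering.

## Relay layer

Three relays authenticate each submission (app token plus known account)
and hold retention-bounded queues (default **7 days**, the window available
to recover the ledger before data loss).  The app selects two of the three
relays uniformly at random per delivery attempt, and dequeues a record only
when both selected relays accept; a partial acceptance is abandoned and the
whole pair retried with a fresh selection.  This atomic-pair rule is what
keeps the "exactly two copies" verification condition satisfiable under
partial failure — without it, a half-delivered record retried to a
different pair could legitimately end up on three relays.  Queue age is
evaluated against the simulated clock at dispatch time, so expiry is
reproducible.

## Ledger

Transactions pass through the permissioned-blockchain lifecycle: proposal,
endorsement by each organization (well-formed, not already submitted, valid
credential, append-only operation), a 2-of-3 endorsement policy at
submission, chronological ordering with ties broken by transaction id, and
block cutting (up to 10 transactions per block) committed to every healthy
peer.  Choices worth noting:

* The transaction id hashes the envelope bytes together with the relay id,
  so the two intended relay copies are distinct transactions and the
  duplicate check does not suppress the second copy.
* The endorsement threshold of 2-of-3 organizations tolerates one whole
  organization's outage without interrupting commits.
* Conflicting *appends* at the same participant/sequence are both
  committed: the ledger is an append-only log, and falsified data that
  reaches it is meant to be stored and then exposed by verification, not
  silently suppressed.  Only update/delete operations are refused at
  endorsement ("not authorized").
* A failed peer keeps its stale chain until the periodic health check
  replaces it with a fresh peer synced from any healthy replica — the
  auto-scaling recovery pattern.  A *total* outage has no healthy sync
  source; recovery within the retention window is modelled as an operator
  restore (`Ledger.revive_all`), which is exactly the window the 7-day
  queue retention exists to provide.
* No consensus protocol is simulated; the externally observable contract
  (total order, byte-identical replication, policy enforcement) is kept.

## Verification protocol

Per participant, over all committed transactions:

* **C1 completeness** — exactly one key-generation record at seq 0, exactly
  one key reveal, and a gap-free run of clinical records between them.
* **C2 hashchain** — records sorted by generation time (ties by seq);
  every registered hash must recompute from the canonical document, the
  revealed key, and a registered hash at the preceding sequence number.
  When several distinct records share a sequence number (a fork planted by
  an attacker), each is checked against every candidate predecessor: the
  genuine record still verifies and only the forgery is flagged, which
  localizes the attack.
* **C3 relay copies** — every sequence number carries exactly two
  byte-identical copies from two distinct relays.  The key-reveal record
  follows the same two-copy rule as every other record (uniformity).

Block linkage of the ledger copy itself is verified by recomputing every
block hash and prev-link.  A participant who never reveals a key (dropout)
is reported *unverifiable* — C2 cannot be evaluated without the key — and
does not fail the trial; C1/C3 are still evaluated and reported for them.
When several conditions fire for one attack, the report lists all of them
and names the lowest-numbered one as the headline, rather than assuming
which mechanism detects first.

## Adversary model and scenarios

The attacker observes every transported byte (envelopes, registered hashes,
the app authentication token) but never an unrevealed secret key, and
cannot invert SHA-256.  Under this model:

* **Impersonation** (stolen account): injected records carry fabricated or
  replayed hashes; recomputation with the true key fails → C2.
* **Relay compromise**: an altered forwarded copy diverges from its
  sibling → C3 (and C2, since the observed hash no longer matches the
  altered payload); a wholly fabricated record has the wrong copy count and
  an unverifiable hash → C3 and C2.
* **Export tampering**: one scalar of one committed transaction in an audit
  copy is minimally mutated (the line stays parseable JSON, so detection is
  verification's job rather than the parser's) → block linkage and C2/C3.
* **Peer failure / outages** are pure fault scenarios: nothing is
  falsified, so verification stays green and the measured quantities are
  lost registrations, error records, expired queue items, and post-recovery
  chain agreement.

Scenarios act at day boundaries of the simulation loop, never on live
intra-day state, so every run is replayable from its seed.

## Synthetic trial generator

The generator emulates participants in a smartphone-based randomized trial:
staggered enrollment within the first week, one questionnaire submission
per 7-day visit interval, arm labels (intervention/control) carried as a
payload field without any modelled treatment effect.  The instrument set is
the six outcome measures such a trial collects — GPAQ, CARS (overall fear
index, 4 items), PHQ-9 (9 items, 0–3), CFS (15 items, 1–5), AIS (8 items,
0–3), EQ-5D (5 dimensions plus a 0–100 VAS) — with item counts and ranges
from the instruments' public definitions.  Answers are drawn uniformly
within range: only payload shape and byte-identity matter to the integrity
machinery, so no response model, scoring, or clinical realism is attempted,
and passing tests say nothing about questionnaire semantics on real data.

Defaults: 100 participants, 10 records each, 7-day visit interval, 5 %
dropout probability.  Every participant draws from an independent
substream of the master seed, so removing one participant never perturbs
another's schedule — a property the tests rely on.  Dropouts stop after a
random number of submissions and never reveal their key; their records are
reported unverifiable, which is the protocol's intended behaviour, not a
failure.

## Problem sizes and numerical choices

* Soundness and redundancy checks run on the full-size honest trial
  (100 × 10, no dropouts — the scenario verifies every participant
  end-to-end, which requires completion).
* Randomized detection sweeps use a 5-participant × 5-record trial per
  repetition (100 impersonations, 100 relay injections, 200 export
  tampers, 20 honest seeds): the detection mechanisms are per-record, so
  small trials exercise them fully while keeping hundreds of repetitions
  cheap.
* The retention-boundary scenario uses 30 participants × 8 records with a
  total outage starting on day 20: weekly visits put only a thin slice of
  traffic into the over-age window, and 30 participants keep that slice
  populated for any seed.  A 6-day outage expires nothing; an 8-day outage
  expires exactly the items older than 7 days at dispatch time.
* The simulated clock starts at a fixed epoch (2019-05-01T00:00:00Z) and
  timestamps render as ISO-8601 UTC with milliseconds; relay pair
  selection, keys, payloads, and schedules all come from named,
  seed-derived substreams, giving byte-identical ledger exports for equal
  seeds.

## Known limitations

* The ledger simulation has no Byzantine peers and no consensus protocol;
  replication is modelled as deterministic broadcast.  Claims about
  consensus-level faults are out of scope.
* Transport security (TLS, IP allow-listing, certificate management) is
  abstracted into the token-based `authenticate` contract.
* The attacker model excludes key exfiltration from the device and
  cryptanalysis of SHA-256; a stolen *key* (not just a stolen account)
  would defeat C2 by construction.
* Questionnaire payloads are shape-realistic only; no missing-item
  patterns, response styles, or treatment effects are modelled.
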