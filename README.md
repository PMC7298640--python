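# trialchain

Tamper-evident data capture for decentralized clinical trials, at desk
scale.

Clinical trials that collect electronic patient-reported outcomes (ePRO)
on participants' own smartphones have a data-integrity problem: between the
moment a participant answers a questionnaire and the moment the record
lands in the trial database, data can be falsified by an impersonated
client, a compromised relay server, or post-hoc edits — and the classical
remedy, 100 % on-site source data verification, is labor-intensive and
expensive.  `trialchain` simulates, end to end, a data-management
architecture that makes such falsification *detectable by computation
alone*:

* **Client hashchain.**  At first login the account is locked and the app
  draws a secret key *s* kept only on the device.  Each record *i* carries
  `h_i = SHA-256(d_i ‖ h_{i-1} ‖ s)` (with `h_0` built from the first
  record and *s* alone).  The key is revealed in a final record when the
  participant completes the trial, enabling retrospective verification of
  the whole chain.
* **Redundant relays.**  Every record is sent to two of three
  authenticated relay servers, selected uniformly at random; relay queues
  retain undelivered records for 7 days.
* **Permissioned ledger.**  Three organizations × two validating peers
  commit endorsed transactions (2-of-3 policy) into hash-linked blocks
  replicated on every peer, with health-check recovery of failed peers.
* **Verification protocol.**  After the trial, per participant: **C1** all
  required record types present without gaps, **C2** every registered hash
  recomputes from the revealed key, **C3** every record has exactly two
  byte-identical copies from distinct relays — plus block-linkage
  verification of the ledger itself.

The package is for anyone studying or teaching verifiable data pipelines
for decentralized trials: it contains the full client/relay/ledger
simulation, the verification protocol, a synthetic-trial generator
(GPAQ, CARS, PHQ-9, CFS, AIS and EQ-5D payloads), and scripted attack and
fault scenarios with measured detection rates.

## Worked example

Simulate a small honest trial, then audit its exported ledger:

```sh
$ trialchain simulate --config demo.yaml --seed 42 --out demo
participants=3 records=18 committed=36 blocks=12

$ trialchain verify demo/ledger.jsonl
participant  complete  C1    C2    C3    records
P0001        True      pass  pass  pass       12
P0002        True      pass  pass  pass       12
P0003        True      pass  pass  pass       12
linkage: ok
overall: PASS
```

with `demo.yaml` containing:

```yaml
n_participants: 3
records_per_participant: 4
dropout_probability: 0.0
```

Each participant produced 1 key-generation + 4 clinical + 1 key-reveal
record; every record was committed twice (once per selected relay), hence
`records=18`, `committed=36`, and 12 transactions per participant.  The
audit recomputed every chain hash from the revealed keys (C2), checked
record completeness (C1) and relay-copy agreement (C3), and re-derived
every block hash (`linkage: ok`).  The `verify` command exits 0 on pass,
1 on any verification failure, 2 on a malformed export.

Now let an attacker with a stolen account inject a forged record:

```sh
$ trialchain attack --config demo.yaml --scenario impersonation.yaml \
      --seed 42 --out demo-atk
{"kind": "IMPERSONATION", "detected": true, "condition": "C2"}
```

The forged record was committed — the ledger is an append-only log — but
its hash cannot be recomputed from the participant's revealed key, so the
hashchain condition C2 flags it (the full report in
`demo-atk/summary.json` names the participant and sequence number).
`fault` runs peer-failure and outage scenarios the same way, and `export`
renders a committed-transaction table from any ledger export.

The same machinery is available as a library:

```python
from trialchain import TrialConfig, run_trial, verify_trial

run = run_trial(TrialConfig(n_participants=100), seed=1)
report = verify_trial(run.ledger)
assert report.overall_pass
```

## Layout

| module | contents |
| --- | --- |
| `trialchain.canonical` | canonical JSON bytes, SHA-256, the keyed chain hash, simulated clock |
| `trialchain.client` | account lock, key generation, record chaining, retry queue |
| `trialchain.relay` | authentication, uniform pair selection, retention-bounded dispatch |
| `trialchain.ledger` | endorse / order / commit lifecycle, replication, health-check recovery, JSONL export |
| `trialchain.verification` | conditions C1–C3, block linkage, trial reports |
| `trialchain.attacks` | impersonation, relay compromise, export tampering, fault scenarios, detection sweeps |
| `trialchain.synthetic` | trial configs, schedules, questionnaire payload generator |
| `trialchain.engine` | day-by-day orchestration of a full run |
| `trialchain.cli` | `simulate`, `verify`, `attack`, `fault`, `export` |

Design notes, parameter choices, and known limitations are in
[`docs/methods.md`](docs/methods.md).
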