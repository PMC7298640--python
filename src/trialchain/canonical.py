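"""Canonical byte serialization and the keyed SHA-256 chain-hash primitive.

Every component that hashes, transports, or compares a record goes through
this module, so that "the same record" always means "the same bytes".

The canonical JSON dialect is: UTF-8, lexicographically sorted keys, minimal
separators (no insignificant whitespace), no NaN/Infinity, integers rendered
without exponent notation and floats in Python's shortest round-trip form.
Allowed values are text, integers, finite decimals, booleans, nested
mappings, and sequences thereof — the shapes a questionnaire payload takes.

The chain hash links a participant's records into a client hashchain:

    h_0 = H(d_0 || SEP || "" || SEP || s)
    h_i = H(d_i || SEP || h_{i-1} || SEP || s)

where ``d_i`` is the canonical encoding of record *i* (answers plus embedded
metadata), ``s`` is the participant's secret key, ``H`` is SHA-256 and
``SEP`` is the single byte 0x1F.  The non-printable separator makes the
three-field concatenation unambiguous (no value can contain 0x1F after JSON
encoding), so distinct (payload, prev, key) triples map to distinct inputs.
"""

from __future__ import annotations

import hashlib
import json
import random
import re
from datetime import datetime, timedelta, timezone
from typing import Any, Mapping

from .errors import EncodingError, FormatError

__all__ = [
    "SEP",
    "GENESIS_HASH",
    "SIM_EPOCH",
    "canonical_encode",
    "canonical_decode",
    "sha256_hex",
    "chain_hash",
    "new_secret_key",
    "is_hex_digest",
    "require_hex_digest",
    "format_timestamp",
    "SimClock",
]

#: Field separator inside the chain-hash preimage (ASCII Unit Separator).
SEP = b"\x1f"

#: prev_block_hash of the genesis block.
GENESIS_HASH = "0" * 64

#: All simulated timestamps are offsets in days from this fixed epoch.
SIM_EPOCH = datetime(2019, 5, 1, tzinfo=timezone.utc)

_HEX64 = re.compile(r"^[0-9a-f]{64}$")

_SCALARS = (str, int, float, bool)


def _validate(value: Any, path: str) -> None:
    if isinstance(value, bool) or isinstance(value, (str, int)):
        return
    if isinstance(value, float):
        if value != value or value in (float("inf"), float("-inf")):
            raise EncodingError(f"non-finite number at {path!r}")
        return
    if isinstance(value, Mapping):
        for key, item in value.items():
            if not isinstance(key, str):
                raise EncodingError(f"non-string field name at {path!r}: {key!r}")
            _validate(item, f"{path}.{key}")
        return
    if isinstance(value, (list, tuple)):
        for i, item in enumerate(value):
            _validate(item, f"{path}[{i}]")
        return
    raise EncodingError(f"unserializable value at {path!r}: {type(value).__name__}")


def canonical_encode(payload: Mapping[str, Any]) -> bytes:
    """Serialize *payload* to canonical UTF-8 JSON bytes.

    Equal payloads (up to field order) always yield identical bytes; the
    encoding is idempotent through :func:`canonical_decode`.
    """
    if not isinstance(payload, Mapping):
        raise EncodingError(f"payload must be a mapping, got {type(payload).__name__}")
    _validate(payload, "$")
    return json.dumps(
        payload, sort_keys=True, separators=(",", ":"), ensure_ascii=False,
        allow_nan=False,
    ).encode("utf-8")


def canonical_decode(data: bytes) -> dict[str, Any]:
    """Inverse of :func:`canonical_encode` (any valid JSON object accepted)."""
    obj = json.loads(data.decode("utf-8"))
    if not isinstance(obj, dict):
        raise EncodingError("canonical document must be a JSON object")
    return obj


def sha256_hex(data: bytes) -> str:
    """FIPS 180-4 SHA-256 digest of *data* as 64 lowercase hex characters."""
    return hashlib.sha256(data).hexdigest()


def is_hex_digest(value: str) -> bool:
    return isinstance(value, str) and bool(_HEX64.match(value))


def require_hex_digest(value: str, what: str) -> str:
    if not is_hex_digest(value):
        raise FormatError(f"{what} must be 64 lowercase hex characters, got {value!r}")
    return value


def chain_hash(payload_bytes: bytes, prev: str, key: str) -> str:
    """Keyed chain hash of one record.

    ``prev`` is the previous record's chain hash, or the empty string for a
    participant's first record.  Returns SHA-256 over
    ``payload_bytes || 0x1F || prev || 0x1F || key`` in lowercase hex.
    """
    if prev != "":
        require_hex_digest(prev, "prev hash")
    require_hex_digest(key, "secret key")
    return sha256_hex(payload_bytes + SEP + prev.encode("ascii") + SEP + key.encode("ascii"))


def new_secret_key(rng: random.Random) -> str:
    """Draw a fresh 256-bit secret key (64 hex chars) from a seeded stream."""
    return rng.randbytes(32).hex()


def format_timestamp(day: float) -> str:
    """Render simulated day offset as ISO-8601 UTC with milliseconds."""
    dt = SIM_EPOCH + timedelta(days=day)
    return dt.strftime("%Y-%m-%dT%H:%M:%S.") + f"{dt.microsecond // 1000:03d}Z"


class SimClock:
    """Discrete simulated clock counting days from :data:`SIM_EPOCH`."""

    def __init__(self, day: float = 0.0) -> None:
        self.day = float(day)

    def advance(self, days: float) -> None:
        self.day += days

    def timestamp(self) -> str:
        return format_timestamp(self.day)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SimClock(day={self.day:.4f})"
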