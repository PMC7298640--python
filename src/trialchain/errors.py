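"""Exception hierarchy shared across the package."""


class TrialchainError(Exception):
    """Base class for all package errors."""


class EncodingError(TrialchainError):
    """Payload contains a value that cannot be canonically serialized."""


class FormatError(TrialchainError):
    """A hex digest or secret key string is malformed."""


class AccountLockedError(TrialchainError):
    """First login attempted on an account that is already locked."""


class UnknownAccountError(TrialchainError):
    """Login attempted with an account id that was never issued."""


class TrialCompletedError(TrialchainError):
    """Record creation or completion attempted after the key reveal."""


class EmptyPayloadError(TrialchainError):
    """Clinical record submitted with no answers."""


class ConfigurationError(TrialchainError):
    """Invalid trial, relay, or scenario configuration."""


class PolicyNotMet(TrialchainError):
    """Transaction gathered fewer endorsements than the policy requires."""


class OrgUnavailable(TrialchainError):
    """No healthy peer in the organization can endorse."""


class LedgerUnavailable(TrialchainError):
    """Too few healthy organizations for any transaction to commit."""


class KeyUnavailable(TrialchainError):
    """Hashchain verification requested without a revealed secret key."""
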