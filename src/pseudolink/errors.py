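"""Exception hierarchy shared across the toolkit."""


class PseudolinkError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(PseudolinkError):
    """A field name is not part of the configured field schema."""


class EmptyIdentityError(PseudolinkError):
    """An identity carries no non-missing field value."""


class UnknownPseudonymTypeError(PseudolinkError):
    """A pseudonym type name is not configured in the store."""


class DuplicatePseudonymError(PseudolinkError):
    """(type_name, value) already assigned to another patient."""


class ImmutablePseudonymError(PseudolinkError):
    """Attempt to edit an internally generated pseudonym."""


class MergeError(PseudolinkError):
    """Invalid merge (self-merge or already-absorbed record)."""


class TentativePairError(PseudolinkError):
    """Pair is not in the store's tentative-match list."""


class ConfigError(PseudolinkError):
    """Invalid configuration value."""


class CapacityError(PseudolinkError):
    """Counter exceeds the capacity of an identifier scheme."""


class CodecError(PseudolinkError):
    """Decoding of an encoded identifier failed (bad key or corrupt input)."""


class DecryptionError(PseudolinkError):
    """Authenticated decryption failed (wrong key or tampered envelope)."""


class LinkageError(PseudolinkError):
    """Record comparison is impossible (no comparable fields)."""


class AuthenticationError(PseudolinkError):
    """Unknown API key."""


class AuthorizationError(PseudolinkError):
    """Operation denied by role permissions or token state."""


class TokenError(PseudolinkError):
    """Token unknown, consumed, expired, or of the wrong type."""


class ConsentError(PseudolinkError):
    """Invalid consent operation (unknown template, missing choice, ...)."""


class BatchError(PseudolinkError):
    """Bulk import/export failure (unmappable header, bad sizes, ...)."""
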