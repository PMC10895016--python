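"""Exception hierarchy shared by all co-simulation modules."""


class CosimError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(CosimError, ValueError):
    """A parameter value violates its documented domain."""


class ValidationError(CosimError, ValueError):
    """Input data (files, matrices, payloads) failed a consistency check."""


class ContractError(CosimError, ValueError):
    """A caller violated an operation's pre-condition."""


class SequencingError(CosimError, RuntimeError):
    """Windows or channel operations were used out of order."""


class IntegrationError(CosimError, RuntimeError):
    """A simulator state became non-finite during integration."""


class InitializationError(CosimError, RuntimeError):
    """History buffers or connections were not prepared before use."""


class ChannelStateError(CosimError, RuntimeError):
    """A channel endpoint was used after release or in the wrong role."""


class BrokenChannelError(CosimError, RuntimeError):
    """The peer endpoint disappeared or was released mid-stream."""


class DeadlockError(CosimError, RuntimeError):
    """A blocking channel operation exceeded its timeout."""


class TransferModuleError(CosimError, RuntimeError):
    """A transfer module aborted (e.g. its transform raised)."""


class EndOfStream(CosimError):
    """Raised by a receive endpoint after the peer ended the transfer and
    all buffered windows have been drained.  Not an error condition."""
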