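"""Exception types shared across the package."""


class ClusterTreeError(Exception):
    """A user-facing input or configuration error.

    The CLI converts these into one-line diagnostics instead of tracebacks.
    """


class InvariantError(ClusterTreeError):
    """An internal consistency requirement was violated (e.g. an empty cluster node)."""
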