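"""Exception hierarchy.

``ValidationError`` aborts a run before any data is touched (bad MDT, bad
config). ``RowRejected`` is raised for a single bad data row; pipelines catch
it, record the row in the track's rejects sidecar and keep going.
"""


class HarmonizeError(Exception):
    """Base class for all package errors."""


class ValidationError(HarmonizeError):
    """Configuration or metadata failed validation; nothing was processed."""


class RowRejected(HarmonizeError):
    """A single data row could not be harmonized.

    Parameters
    ----------
    reason : str
        Human-readable category, e.g. ``"short-row"`` or ``"unresolved-alleles"``.
    detail : str, optional
        Free-text context appended to the rejects report.
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        self.detail = detail
        super().__init__(f"{reason}: {detail}" if detail else reason)
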