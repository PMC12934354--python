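"""Exception hierarchy for the famec codec."""


class FamecError(Exception):
    """Base class for all famec errors."""


class MalformedInputError(FamecError):
    """An input FASTA file violates the format assumptions.

    Carries the offending path and, where known, the byte offset.
    """

    def __init__(self, message: str, path: str | None = None, offset: int | None = None):
        self.path = path
        self.offset = offset
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f" @ byte {offset}]" if offset is not None else "]")
        super().__init__(message + loc)


class CorruptArchiveError(FamecError):
    """The archive bytes are inconsistent with the container format."""


class TruncatedArchiveError(CorruptArchiveError):
    """The archive ends before a declared section or payload is complete."""


class HashMismatchError(CorruptArchiveError):
    """A restored file's content hash differs from the recorded one."""

    def __init__(self, path: str):
        self.path = path
        super().__init__(f"content hash mismatch for restored file {path!r}")


class StreamUnderrunError(CorruptArchiveError):
    """A logical stream ran out of tokens while decoding a contig."""

    def __init__(self, stream: str, offset: int):
        self.stream = stream
        self.offset = offset
        super().__init__(f"stream {stream!r} exhausted at token offset {offset}")


class NotFoundError(FamecError):
    """A selector matched no file in the archive."""


class DuplicatePathError(FamecError):
    """An appended file path already exists in the archive."""


class ReferenceCapError(FamecError):
    """The reference buffer would exceed the configured memory cap."""

    def __init__(self, cap: int):
        self.cap = cap
        super().__init__(
            f"reference buffer would exceed the configured cap of {cap} bytes; "
            "rerun with a larger --ref-cap"
        )
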