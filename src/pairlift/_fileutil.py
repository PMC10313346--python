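"""Small file helpers shared across modules."""

from __future__ import annotations

import gzip
import io
import os
from contextlib import contextmanager
from typing import IO, Iterator, Union

PathOrHandle = Union[str, os.PathLike, IO[str]]

_GZIP_MAGIC = b"\x1f\x8b"


def _is_gzip(path: str | os.PathLike) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == _GZIP_MAGIC


@contextmanager
def open_text(source: PathOrHandle, mode: str = "r") -> Iterator[IO[str]]:
    """Yield a text handle for ``source``.

    Paths are opened directly; gzip files are detected by magic bytes
    (never by extension) when reading.  Existing handles pass through
    unclosed so callers can wrap ``io.StringIO`` in tests.
    """
    if hasattr(source, "read") or hasattr(source, "write"):
        yield source  # type: ignore[misc]
        return
    if "r" in mode and _is_gzip(source):
        with gzip.open(source, "rt") as fh:
            yield fh
        return
    with open(source, mode) as fh:
        yield fh
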