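"""Shared helpers: coded warnings and strict-mode promotion."""

from __future__ import annotations

import contextlib
import warnings


class MkgpWarning(UserWarning):
    """Package warning carrying a machine-readable code."""

    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"[{code}] {message}")


def warn(code: str, message: str, stacklevel: int = 2) -> None:
    warnings.warn(MkgpWarning(code, message), stacklevel=stacklevel + 1)


@contextlib.contextmanager
def strict_warnings(enabled: bool = True):
    """Promote coded warnings to errors (strict mode)."""
    with warnings.catch_warnings():
        if enabled:
            warnings.simplefilter("error", MkgpWarning)
        yield
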