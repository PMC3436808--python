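"""Small internal helpers."""

from __future__ import annotations

import contextlib
import ctypes
import os
import sys


def _flush_c_streams() -> None:
    try:
        libc = ctypes.CDLL(None)
        libc.fflush(None)
    except (OSError, AttributeError):  # pragma: no cover
        pass


@contextlib.contextmanager
def silence_native_output():
    """Suppress stdout/stderr emitted below the Python layer.

    The bundled HiGHS build prints a stray diagnostic line from its MIP
    postsolve even with display off; it writes directly to the C-level file
    descriptors, so plain ``redirect_stdout`` cannot catch it.
    """
    try:
        sys.stdout.flush()
        sys.stderr.flush()
        saved_out = os.dup(1)
        saved_err = os.dup(2)
    except (OSError, ValueError):  # pragma: no cover - exotic streams
        yield
        return
    devnull = os.open(os.devnull, os.O_WRONLY)
    try:
        os.dup2(devnull, 1)
        os.dup2(devnull, 2)
        yield
    finally:
        _flush_c_streams()
        os.dup2(saved_out, 1)
        os.dup2(saved_err, 2)
        os.close(devnull)
        os.close(saved_out)
        os.close(saved_err)
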