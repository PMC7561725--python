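"""Small shared helpers: atomic file writes, seed fan-out, logging."""

from __future__ import annotations

import logging
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import numpy as np

logger = logging.getLogger("lncscreen")


@contextmanager
def atomic_open(path: str | os.PathLike, mode: str = "w"):
    """Write to a temp file in the target directory, rename into place on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive `n` independent per-stage seeds (< 2**31) from one global seed.

    Uses numpy's SeedSequence so stages are independently reproducible from
    (seed, stage index) alone.
    """
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1, np.uint32)[0] % (2**31)) for child in ss.spawn(n)]


def rng_from(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed))
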