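"""WAV and table I/O helpers (mono float WAV via scipy)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.io import wavfile

from songphys.audio import Waveform
from songphys.errors import DataError


def write_wav(path: str | Path, w: Waveform) -> None:
    """Write a mono float32 PCM WAV file."""
    wavfile.write(str(path), int(round(w.rate)), w.samples.astype(np.float32))


def read_wav(path: str | Path) -> Waveform:
    """Read a mono WAV file; integer PCM is rescaled to [-1, 1)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"WAV file not found: {path}")
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise DataError(f"{path} is not mono")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max + 1)
    return Waveform(np.asarray(data, dtype=np.float64), float(rate))
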