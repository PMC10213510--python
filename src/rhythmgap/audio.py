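"""WAV read/write (PCM16 and float32) and Audacity-style label files."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = ["read_wav", "write_wav", "read_labels", "write_labels"]


def read_wav(path: str | Path) -> tuple[float, np.ndarray]:
    """Read a WAV file; integer PCM is scaled to float in [-1, 1]."""
    rate, data = wavfile.read(str(path))
    if data.dtype.kind == "i":
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":  # 8-bit unsigned PCM
        data = (data.astype(float) - 128.0) / 127.0
    else:
        data = data.astype(float)
    return float(rate), data


def write_wav(path: str | Path, rate: float, data: np.ndarray,
              subtype: str = "pcm16") -> None:
    """Write a mono/stereo WAV file as PCM16 (default) or float32."""
    data = np.asarray(data)
    if subtype == "pcm16":
        clipped = np.clip(data, -1.0, 1.0)
        wavfile.write(str(path), int(rate), (clipped * 32767.0).astype(np.int16))
    elif subtype == "float32":
        wavfile.write(str(path), int(rate), data.astype(np.float32))
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")


def read_labels(path: str | Path) -> list[tuple[float, float, str]]:
    """Read `start_s<TAB>end_s<TAB>label` lines (Audacity label dialect)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        start, end, label = line.split("\t", 2)
        out.append((float(start), float(end), label))
    return out


def write_labels(path: str | Path, labels: list[tuple[float, float, str]]) -> None:
    Path(path).write_text(
        "".join(f"{s:.6f}\t{e:.6f}\t{lab}\n" for s, e, lab in labels)
    )
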