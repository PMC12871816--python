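"""Binary trajectory container.

Layout (little-endian), in file order:

=========  =======  ===========================================
bytes      type     meaning
=========  =======  ===========================================
12         bytes    magic string ``b"TAILGATETRJ1"``
4          uint32   atom count N
8          uint64   frame count F
4          uint32   output stride (steps between frames)
8          int64    RNG seed of the run that produced the file
8          float64  time of frame 0 (tau)
8          float64  time between frames (tau)
2          uint16   length L of the config digest
L          bytes    config digest, UTF-8
F*N*3*4    float32  frames, C order (frame, atom, xyz), nm
=========  =======  ===========================================

Coordinates are stored as 32-bit floats; analysis tolerances in this
package are no tighter than 1e-6 nm, which float32 comfortably satisfies
for corridor-scale coordinates.
"""

from __future__ import annotations

import struct
from typing import IO

import numpy as np

from .errors import TrajectoryCorruptionError, TrajectoryFormatError
from .structure import Trajectory

MAGIC = b"TAILGATETRJ1"
_HEADER = struct.Struct("<IQIqddH")


def write_trajectory(t: Trajectory, sink: IO[bytes]) -> None:
    """Serialize a validated Trajectory to a binary sink."""
    t.validate()
    dt_frame = float(t.times[1] - t.times[0]) if t.n_frames >= 2 else 0.0
    digest = t.config_digest.encode()
    sink.write(MAGIC)
    sink.write(_HEADER.pack(t.n_atoms, t.n_frames, t.output_stride,
                            int(t.seed), float(t.times[0]), dt_frame,
                            len(digest)))
    sink.write(digest)
    sink.write(np.ascontiguousarray(t.frames, dtype=np.float32).tobytes())


def read_trajectory(source: IO[bytes]) -> Trajectory:
    """Read a trajectory container, verifying magic and payload size."""
    magic = source.read(len(MAGIC))
    if magic != MAGIC:
        raise TrajectoryFormatError(
            f"bad magic string {magic!r}; not a tailgate trajectory")
    header = source.read(_HEADER.size)
    if len(header) < _HEADER.size:
        raise TrajectoryCorruptionError("truncated header")
    n_atoms, n_frames, stride, seed, t0, dt_frame, digest_len = \
        _HEADER.unpack(header)
    digest = source.read(digest_len)
    if len(digest) < digest_len:
        raise TrajectoryCorruptionError("truncated config digest")
    payload = source.read(n_frames * n_atoms * 3 * 4)
    extra = source.read(1)
    n_floats = len(payload) // 4
    if n_floats < n_frames * n_atoms * 3:
        frame = n_floats // (n_atoms * 3) if n_atoms else 0
        raise TrajectoryCorruptionError(
            f"truncated payload at frame {frame} of {n_frames}")
    if extra:
        raise TrajectoryCorruptionError(
            "trailing bytes after declared frame payload")
    frames = np.frombuffer(payload, dtype="<f4").reshape(n_frames, n_atoms, 3)
    times = t0 + dt_frame * np.arange(n_frames, dtype=np.float64)
    return Trajectory(times=times, frames=np.array(frames, dtype=np.float64),
                      seed=int(seed), config_digest=digest.decode(),
                      output_stride=int(stride)).validate()
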