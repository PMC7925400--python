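"""Raster and multimeter file I/O.

Raster format: two-column whitespace-separated ASCII, one event per line
(``sender_id time_ms``), preceded by a comment header recording dt and seed.
Multimeter format: three columns ``time_ms node_id value``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_raster", "read_raster", "RasterParseError",
           "write_multimeter"]


class RasterParseError(ValueError):
    def __init__(self, path, bad_lines):
        self.bad_lines = bad_lines
        preview = ", ".join(str(n) for n, _ in bad_lines[:5])
        super().__init__(f"{path}: malformed raster lines {preview}"
                         + ("..." if len(bad_lines) > 5 else ""))


def write_raster(path, senders, times, dt=None, seed=None):
    """Write (sender, time) events; times are printed exactly at full precision."""
    with open(path, "w") as fh:
        fh.write(f"# spikesim raster dt={dt} seed={seed}\n")
        for s, t in zip(senders, times):
            fh.write(f"{int(s)} {float(t):.10g}\n")


def read_raster(path):
    """Read a raster file; returns (senders, times, meta dict).

    Malformed lines are collected and reported with their line numbers.
    A file containing only the header is a valid empty raster.
    """
    senders, times, bad = [], [], []
    meta = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        try:
                            meta[k] = float(v)
                        except ValueError:
                            meta[k] = v
                continue
            parts = line.split()
            try:
                if len(parts) != 2:
                    raise ValueError
                senders.append(int(parts[0]))
                times.append(float(parts[1]))
            except ValueError:
                bad.append((ln, line))
    if bad:
        raise RasterParseError(path, bad)
    return (np.asarray(senders, dtype=np.int64), np.asarray(times),
            meta)


def write_multimeter(path, times, node_ids, values):
    """Columnar ASCII dump of multimeter samples (time_ms node_id value)."""
    with open(path, "w") as fh:
        fh.write("# spikesim multimeter time_ms node_id value\n")
        for t, row in zip(times, values):
            for nid, v in zip(node_ids, row):
                fh.write(f"{float(t):.10g} {int(nid)} {float(v):.10g}\n")
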