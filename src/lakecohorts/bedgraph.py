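"""Reading and writing windowed depth profiles as BedGraph.

BedGraph here is the plain 4-column text format: ``contig  start  end  depth``
with 0-based, half-open coordinates. Depth is constant over an interval;
consecutive windows with equal depth are merged on write and re-expanded on
read. Contig names are genome ids, one file per sample.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import InputError


def write_bedgraph(path: str | Path, profiles: dict[str, np.ndarray], window: int) -> None:
    """Write per-genome windowed depth vectors to one BedGraph file.

    ``profiles`` maps genome id to a 1-D depth vector (one value per
    ``window``-bp window). Runs of equal depth are merged into single
    intervals. A genome with an all-zero profile is still emitted (as a
    single zero interval) so downstream prevalence denominators are
    unambiguous.
    """
    with open(path, "w") as fh:
        for genome in sorted(profiles):
            depths = np.asarray(profiles[genome])
            if depths.ndim != 1 or depths.size == 0:
                raise InputError(f"profile for {genome!r} must be a non-empty 1-D vector")
            change = np.flatnonzero(np.diff(depths)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [depths.size]))
            vals = depths[starts]
            for s, e, v in zip(starts, ends, vals):
                fh.write(f"{genome}\t{s * window}\t{e * window}\t{_fmt(v)}\n")


def _fmt(v) -> str:
    f = float(v)
    return str(int(f)) if f == int(f) else repr(f)


def read_bedgraph(path: str | Path, window: int) -> dict[str, np.ndarray]:
    """Read a BedGraph file back into per-genome windowed depth vectors.

    Interval bounds must be multiples of ``window`` and intervals of each
    contig must tile it contiguously from 0 (which is how this package
    writes them).
    """
    raw: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise InputError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            contig, start, end, depth = parts
            raw.setdefault(contig, []).append((int(start), int(end), float(depth)))
    profiles: dict[str, np.ndarray] = {}
    for contig, intervals in raw.items():
        intervals.sort()
        pos = 0
        chunks = []
        for start, end, depth in intervals:
            if start != pos or start % window or end % window or end <= start:
                raise InputError(
                    f"{path}: contig {contig!r} intervals do not tile the genome in {window}-bp windows"
                )
            chunks.append(np.full((end - start) // window, depth))
            pos = end
        profiles[contig] = np.concatenate(chunks)
    return profiles
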