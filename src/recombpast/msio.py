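"""Reading and writing the ms output format.

The format of Hudson's ms: an optional command-echo line and seed line,
then replicates separated by ``//``, each with ``segsites: k``, a
``positions:`` line of relative positions in [0, 1), and one 0/1 row per
sampled haplotype.  ``segsites: 0`` replicates carry no positions line and
no rows; on reading, the sample size is then taken from the command-echo
header (or from sibling replicates) so the empty matrix keeps its row count.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import IO, Iterable, List, Sequence, Union

import numpy as np

from .coalsim import HaplotypeDataset

__all__ = ["write_ms", "read_ms"]

Source = Union[str, Path, IO[str]]


def write_ms(datasets: Sequence[HaplotypeDataset], sink: Source,
             precision: int = 6) -> None:
    """Write datasets as one ms-format stream (one replicate each)."""
    datasets = list(datasets)
    own = isinstance(sink, (str, Path))
    fh: IO[str] = open(sink, "w") if own else sink  # type: ignore[arg-type]
    try:
        n = datasets[0].sample_n if datasets else 0
        fh.write(f"ms {n} {len(datasets)}\n")
        fh.write("0 0 0\n")
        for ds in datasets:
            fh.write("\n//\n")
            fh.write(f"segsites: {ds.n_sites}\n")
            if ds.n_sites:
                fh.write("positions: " +
                         " ".join(f"{p:.{precision}f}" for p in ds.positions) +
                         "\n")
                for row in ds.matrix:
                    fh.write("".join("1" if v else "0" for v in row) + "\n")
    finally:
        if own:
            fh.close()


def _iter_lines(source: Source) -> Iterable[str]:
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.exists():
            with open(p) as fh:
                yield from fh
            return
        if isinstance(source, str) and ("\n" in source or "//" in source):
            yield from io.StringIO(source)
            return
        raise FileNotFoundError(source)
    yield from source


def read_ms(source: Source) -> List[HaplotypeDataset]:
    """Parse ms-format text (a path, a file object, or the text itself)."""
    lines = [ln.rstrip("\n") for ln in _iter_lines(source)]
    header_n = None
    if lines and lines[0].split()[:1] == ["ms"]:
        parts = lines[0].split()
        if len(parts) >= 2 and parts[1].isdigit():
            header_n = int(parts[1])

    datasets: List[HaplotypeDataset] = []
    i = 0
    pending_empty: List[int] = []  # indices of segsites-0 replicates
    while i < len(lines):
        if lines[i].strip() != "//":
            i += 1
            continue
        i += 1
        while i < len(lines) and not lines[i].startswith("segsites:"):
            if lines[i].strip() and lines[i].strip() != "//":
                raise ValueError(f"expected 'segsites:' after '//', got {lines[i]!r}")
            i += 1
        if i >= len(lines):
            raise ValueError("replicate truncated before 'segsites:'")
        segsites = int(lines[i].split(":", 1)[1])
        i += 1
        if segsites == 0:
            pending_empty.append(len(datasets))
            datasets.append(HaplotypeDataset(
                matrix=np.zeros((header_n or 0, 0), np.uint8),
                positions=np.zeros(0), sample_n=header_n or 0))
            continue
        while i < len(lines) and not lines[i].startswith("positions:"):
            if lines[i].strip():
                raise ValueError(f"expected 'positions:' line, got {lines[i]!r}")
            i += 1
        if i >= len(lines):
            raise ValueError("replicate truncated before 'positions:'")
        positions = np.array([float(tok) for tok in
                              lines[i].split(":", 1)[1].split()])
        if len(positions) != segsites:
            raise ValueError("positions count does not match segsites")
        i += 1
        rows: List[List[int]] = []
        while i < len(lines) and lines[i].strip() and lines[i].strip() != "//":
            row = lines[i].strip()
            if set(row) - {"0", "1"}:
                raise ValueError(f"non-binary haplotype row: {row!r}")
            if segsites and len(row) != segsites:
                raise ValueError("ragged haplotype row")
            rows.append([1 if ch == "1" else 0 for ch in row])
            i += 1
        if not rows:
            raise ValueError("replicate has segregating sites but no rows")
        datasets.append(HaplotypeDataset(
            matrix=np.array(rows, np.uint8), positions=positions,
            sample_n=len(rows)))
    if pending_empty and header_n is None:
        n_other = {d.sample_n for d in datasets if d.n_sites > 0}
        if len(n_other) == 1:
            n = n_other.pop()
            for idx in pending_empty:
                datasets[idx] = HaplotypeDataset(
                    matrix=np.zeros((n, 0), np.uint8),
                    positions=np.zeros(0), sample_n=n)
    return datasets
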