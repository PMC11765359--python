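"""File formats: string lists, composition tables (TSV/JSON), class output.

Strings files are plain text, one 0/1 string per line; ``#`` comments and
blank lines are ignored; duplicate lines are meaningful (multiset).
Composition tables are TSV with ``#n=<int>`` / ``#h=<int>`` header comments
followed by ``l<TAB>w<TAB>count`` rows (omitted cells are zero), or an
equivalent JSON object ``{"n":..., "h":..., "counts":[[l,w,c],...]}``.
Reconstruction classes are JSON Lines, one sorted canonical class per line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .cwf import CWF
from .strings import (
    CompositionMultiset,
    InvalidCompositionsError,
    StringMultiset,
    require_valid,
)

__all__ = [
    "read_strings",
    "write_strings",
    "read_compositions",
    "write_compositions",
    "write_cwf",
    "read_classes",
    "write_classes",
]


def read_strings(path: str | Path) -> StringMultiset:
    """Read a string multiset from a text file (one binary string per line)."""
    lines = Path(path).read_text().splitlines()
    strings = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if set(line) - {"0", "1"}:
            raise ValueError(f"{path}:{lineno}: not a binary string: {raw.strip()!r}")
        strings.append(line)
    if not strings:
        raise ValueError(f"{path}: no strings found")
    try:
        return StringMultiset.from_strings(strings)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_strings(U: StringMultiset, path: str | Path) -> None:
    Path(path).write_text("".join(f"{t}\n" for t in U.members))


def read_compositions(path: str | Path) -> CompositionMultiset:
    """Read and validate a composition table (TSV or JSON, by content).

    The a[0,0] = 2h cell is synthesized from the ``h`` header, never read.
    Raises :class:`InvalidCompositionsError` with the full validation report
    if the table cannot arise from any string multiset.
    """
    text = Path(path).read_text()
    if text.lstrip().startswith("{"):
        obj = json.loads(text)
        n, h = int(obj["n"]), int(obj["h"])
        counts = [(int(l), int(w), int(c)) for l, w, c in obj["counts"]]
    else:
        n = h = None
        counts = []
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                head = line[1:].replace(" ", "")
                if head.startswith("n="):
                    n = int(head[2:])
                elif head.startswith("h="):
                    h = int(head[2:])
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'l w count', got {raw!r}")
            counts.append(tuple(int(x) for x in fields))
        if n is None or h is None:
            raise ValueError(f"{path}: missing '#n=' or '#h=' header")
    a = np.zeros((n + 1, n + 1), dtype=np.int64)
    for l, w, c in counts:
        if not (1 <= l <= n and 0 <= w <= n):
            raise ValueError(f"{path}: cell (l={l}, w={w}) outside the grid")
        a[l, w] += c
    M = CompositionMultiset.from_grid(n, h, a)
    require_valid(M)
    return M


def write_compositions(M: CompositionMultiset, path: str | Path) -> None:
    """Write a composition table as sparse TSV (zero cells omitted)."""
    lines = [f"#n={M.n}", f"#h={M.h}"]
    for l in range(1, M.n + 1):
        for w in range(0, l + 1):
            if M.a[l, w]:
                lines.append(f"{l}\t{w}\t{int(M.a[l, w])}")
    Path(path).write_text("".join(f"{line}\n" for line in lines))


def write_cwf(f: CWF, path: str | Path) -> None:
    """Debug dump of a CWF: one row per label m with its values over l=0..n."""
    lines = [f"#n={f.n}", f"#h={f.h}"]
    for m in range(1, 2 * f.h + 1):
        row = "\t".join(str(int(v)) for v in f.component(m))
        lines.append(f"{m}\t{row}")
    Path(path).write_text("".join(f"{line}\n" for line in lines))


def write_classes(classes: list[tuple[str, ...]], path: str | Path) -> None:
    """Write reconstruction classes as JSON Lines (one sorted array per line)."""
    Path(path).write_text(
        "".join(json.dumps(list(cls)) + "\n" for cls in classes)
    )


def read_classes(path: str | Path) -> list[tuple[str, ...]]:
    return [
        tuple(json.loads(line))
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]
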