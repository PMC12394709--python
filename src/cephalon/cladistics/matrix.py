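"""Binary morphological character matrices and NEXUS I/O.

Characters are binary presence/absence scores over taxa, with ``?`` for
missing/inapplicable entries.  Internally states are int8: 0, 1, and -1 for
missing.  Per-character weights (used by successive reweighting and by the
bootstrap, where a resampled matrix is represented as integer multiplicity
weights) default to 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

__all__ = ["CharacterMatrix", "read_nexus", "write_nexus"]

MISSING = -1


@dataclass
class CharacterMatrix:
    """Taxa x binary-characters table with missing entries and weights."""

    taxa: list[str]
    chars: np.ndarray  # (n_taxa, n_chars) int8 over {0, 1, -1}
    weights: np.ndarray | None = None  # (n_chars,) nonnegative reals
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.chars = np.asarray(self.chars, dtype=np.int8)
        if self.chars.ndim != 2:
            raise ValueError("character table must be 2-D (taxa x characters)")
        if len(self.taxa) != self.chars.shape[0]:
            raise ValueError("taxon count does not match table rows")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        bad = ~np.isin(self.chars, (0, 1, MISSING))
        if bad.any():
            raise ValueError("states must be 0, 1 or missing (?)")
        if self.weights is None:
            self.weights = np.ones(self.chars.shape[1])
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (self.chars.shape[1],) or (self.weights < 0).any():
            raise ValueError("weights must be one nonnegative value per character")
        if self.labels is None:
            self.labels = [f"char_{i + 1}" for i in range(self.chars.shape[1])]

    @property
    def n_taxa(self) -> int:
        return self.chars.shape[0]

    @property
    def n_chars(self) -> int:
        return self.chars.shape[1]

    def column(self, i: int) -> np.ndarray:
        return self.chars[:, i]

    def with_weights(self, weights: np.ndarray) -> "CharacterMatrix":
        return CharacterMatrix(self.taxa, self.chars.copy(), np.asarray(weights, float), list(self.labels))

    def resample(self, rng: np.random.Generator) -> "CharacterMatrix":
        """Bootstrap pseudo-matrix: original columns with multiplicity weights.

        Sampling respects existing weights (a character of weight w is drawn
        with probability proportional to w), and the returned weights are the
        draw counts scaled back by the original weights' unit.
        """
        n = self.n_chars
        p = self.weights / self.weights.sum()
        counts = rng.multinomial(n, p)
        return self.with_weights(counts.astype(float))

    def informative_mask(self) -> np.ndarray:
        """Parsimony-informative characters: >= 2 states each seen >= 2 times."""
        out = np.zeros(self.n_chars, dtype=bool)
        for i in range(self.n_chars):
            col = self.chars[:, i]
            c0 = int((col == 0).sum())
            c1 = int((col == 1).sum())
            out[i] = c0 >= 2 and c1 >= 2
        return out

    def to_strings(self) -> list[str]:
        sym = {0: "0", 1: "1", MISSING: "?"}
        return ["".join(sym[int(s)] for s in row) for row in self.chars]


def read_nexus(path: str | Path) -> CharacterMatrix:
    """Read a NEXUS DATA/CHARACTERS block of 0/1/? standard characters."""
    path = Path(path)
    try:
        dmat = dendropy.StandardCharacterMatrix.get(
            path=str(path), schema="nexus", preserve_underscores=True
        )
    except Exception as exc:  # surface the parser's line-numbered message
        raise ValueError(f"NEXUS parse error in {path.name}: {exc}") from exc
    taxa: list[str] = []
    rows: list[list[int]] = []
    for taxon in dmat.taxon_namespace:
        seq = dmat[taxon]
        taxa.append(taxon.label)
        row = []
        for cell in seq:
            s = str(cell)
            if s == "?" or s == "-":
                row.append(MISSING)
            elif s in ("0", "1"):
                row.append(int(s))
            else:
                raise ValueError(
                    f"NEXUS parse error in {path.name}: state {s!r} outside 01?"
                )
        rows.append(row)
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"NEXUS parse error in {path.name}: ragged rows {sorted(lengths)}")
    weights = _read_weights(path, len(rows[0]))
    return CharacterMatrix(taxa, np.array(rows, dtype=np.int8), weights)


_WTSET_RE = re.compile(r"wtset\s+\*?\s*\S+\s*=([^;]*);", re.IGNORECASE | re.DOTALL)


def _read_weights(path: Path, n_chars: int) -> np.ndarray | None:
    """Parse an ASSUMPTIONS wtset of the simple form ``w: i j k, ...``."""
    text = path.read_text()
    m = _WTSET_RE.search(text)
    if not m:
        return None
    weights = np.ones(n_chars)
    for part in m.group(1).split(","):
        part = part.strip()
        if not part:
            continue
        w_str, idx_str = part.split(":")
        w = float(w_str)
        for tok in idx_str.split():
            weights[int(tok) - 1] = w
    return weights


def write_nexus(matrix: CharacterMatrix, path: str | Path) -> None:
    """Write a DATA block (symbols 01, missing ?) plus a wtset if non-unit."""
    path = Path(path)
    pad = max(len(t) for t in matrix.taxa) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_chars};",
        '  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;',
        "  MATRIX",
    ]
    for taxon, row in zip(matrix.taxa, matrix.to_strings()):
        safe = taxon if re.fullmatch(r"[\w.]+", taxon) else f"'{taxon}'"
        lines.append(f"    {safe.ljust(pad)} {row}")
    lines += ["  ;", "END;"]
    if not np.allclose(matrix.weights, 1.0):
        groups: dict[float, list[int]] = {}
        for i, w in enumerate(matrix.weights):
            groups.setdefault(float(w), []).append(i + 1)
        parts = ", ".join(
            f"{w:.10g}: " + " ".join(map(str, idx)) for w, idx in sorted(groups.items())
        )
        lines += ["BEGIN ASSUMPTIONS;", f"  WTSET * weights = {parts};", "END;"]
    path.write_text("\n".join(lines) + "\n")
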