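"""In-memory nucleotide alignment with codon-position bookkeeping.

Sequences are stored as IUPAC bitmasks (A=1, C=2, G=4, T=8) so that
ambiguity codes become unions of states and gaps/unknowns become the
full mask for likelihood purposes while being treated as missing by
distance and entropy computations.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import AlignmentFormatError, InvalidArgumentError

#: symbol -> bitmask over (A, C, G, T) = bits (1, 2, 4, 8)
IUPAC_MASK = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
    "-": 0, "?": 0, ".": 0, "X": 0,
}
_MASK_SYMBOL = {v: k for k, v in reversed(list(IUPAC_MASK.items()))}
_MASK_SYMBOL[0] = "-"
_MASK_SYMBOL[15] = "N"

#: masks corresponding to a single unambiguous base
UNAMBIGUOUS = {1: 0, 2: 1, 4: 2, 8: 3}

_ENCODE_LUT = np.zeros(256, dtype=np.uint8)
_ENCODE_VALID = np.zeros(256, dtype=bool)
for _sym, _m in IUPAC_MASK.items():
    for _s in (_sym, _sym.lower()):
        _ENCODE_LUT[ord(_s)] = _m
        _ENCODE_VALID[ord(_s)] = True

_BASE_INDEX_LUT = np.full(16, -1, dtype=np.int8)
for _m, _i in UNAMBIGUOUS.items():
    _BASE_INDEX_LUT[_m] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an IUPAC nucleotide string into a bitmask array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if not _ENCODE_VALID[raw].all():
        bad = chr(raw[~_ENCODE_VALID[raw]][0])
        raise AlignmentFormatError(f"unrecognized nucleotide symbol {bad!r}")
    return _ENCODE_LUT[raw]


def decode_sequence(codes: np.ndarray) -> str:
    return "".join(_MASK_SYMBOL[int(c)] for c in codes)


@dataclass
class Alignment:
    """An aligned nucleotide matrix with a codon-position map.

    Parameters
    ----------
    taxa
        Ordered, unique taxon labels.
    codes
        uint8 bitmask matrix of shape ``(n_taxa, n_sites)``.
    codon_map
        int array of shape ``(n_sites,)`` with entries in {1, 2, 3}.
    """

    taxa: list[str]
    codes: np.ndarray
    codon_map: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2:
            raise AlignmentFormatError("alignment matrix must be 2-D")
        if len(self.taxa) != self.codes.shape[0]:
            raise AlignmentFormatError("taxon count does not match matrix rows")
        if len(self.taxa) < 2:
            raise AlignmentFormatError("alignment needs at least 2 taxa")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentFormatError(f"duplicate taxon labels: {dupes}")
        if self.codon_map is None:
            self.codon_map = codon_map_for(self.n_sites, frame_offset=0)
        self.codon_map = np.asarray(self.codon_map, dtype=np.int8)
        if self.codon_map.shape != (self.n_sites,):
            raise AlignmentFormatError("codon_map must cover every site")
        if not np.isin(self.codon_map, (1, 2, 3)).all():
            raise AlignmentFormatError("codon_map entries must be 1, 2 or 3")

    # -- construction ---------------------------------------------------
    @classmethod
    def from_strings(cls, taxa: Sequence[str], rows: Sequence[str],
                     codon_map: np.ndarray | None = None) -> "Alignment":
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise AlignmentFormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        codes = np.vstack([encode_sequence(r) for r in rows])
        return cls(list(taxa), codes, codon_map)

    # -- basic queries ---------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.codes[self.taxa.index(taxon)]

    def sequences(self) -> dict[str, str]:
        return {t: decode_sequence(self.codes[i]) for i, t in enumerate(self.taxa)}

    def base_indices(self) -> np.ndarray:
        """Matrix of base indices 0-3, or -1 where ambiguous/missing."""
        return _BASE_INDEX_LUT[self.codes]

    def base_frequencies(self) -> np.ndarray:
        """Empirical A/C/G/T frequencies over unambiguous cells."""
        idx = self.base_indices()
        counts = np.bincount(idx[idx >= 0].ravel(), minlength=4).astype(float)
        total = counts.sum()
        if total == 0:
            raise AlignmentFormatError("alignment has no unambiguous bases")
        return counts / total

    def variable_site_mask(self) -> np.ndarray:
        """True for columns with >=2 distinct unambiguous bases."""
        idx = self.base_indices()
        out = np.zeros(self.n_sites, dtype=bool)
        for s in range(self.n_sites):
            col = idx[:, s]
            col = col[col >= 0]
            out[s] = col.size > 0 and np.unique(col).size > 1
        return out

    def proportion_invariant(self) -> float:
        """Fraction of columns with no observed variation (fast +I guess)."""
        return 1.0 - self.variable_site_mask().mean()

    # -- slicing ---------------------------------------------------------
    def subset_taxa(self, keep: Iterable[str]) -> "Alignment":
        keep = list(keep)
        missing = [t for t in keep if t not in self.taxa]
        if missing:
            raise InvalidArgumentError(f"taxa not in alignment: {missing}")
        rows = [self.taxa.index(t) for t in keep]
        return Alignment(keep, self.codes[rows].copy(), self.codon_map.copy())

    def subset_sites(self, site_mask: np.ndarray) -> "Alignment":
        site_mask = np.asarray(site_mask)
        if site_mask.dtype == bool:
            cols = np.flatnonzero(site_mask)
        else:
            cols = site_mask.astype(int)
        return Alignment(list(self.taxa), self.codes[:, cols].copy(),
                         self.codon_map[cols].copy())

    def codon_partition(self, positions: Iterable[int]) -> "Alignment":
        positions = set(positions)
        return self.subset_sites(np.isin(self.codon_map, list(positions)))

    # -- pattern compression ----------------------------------------------
    def site_patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique site patterns and their multiplicities.

        Returns
        -------
        patterns : uint8 array of shape (n_patterns, n_taxa)
        weights : float array of shape (n_patterns,)
        """
        patterns, counts = np.unique(self.codes.T, axis=0, return_counts=True)
        return patterns, counts.astype(float)


def codon_map_for(n_sites: int, frame_offset: int = 0) -> np.ndarray:
    """Codon position (1/2/3) per 0-based site given a reading-frame offset.

    ``frame_offset=k`` means the first column is codon position ``k+1``.
    """
    if frame_offset not in (0, 1, 2):
        raise InvalidArgumentError("frame_offset must be 0, 1 or 2")
    return (((np.arange(n_sites) + frame_offset) % 3) + 1).astype(np.int8)


# -- file formats ---------------------------------------------------------

def write_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, seq in aln.sequences().items():
            fh.write(f">{taxon}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_alignment(path: str | Path, fmt: str = "fasta",
                   frame_offset: int = 0) -> Alignment:
    """Read a FASTA or NEXUS alignment (interleaved NEXUS supported)."""
    import dendropy

    path = Path(path)
    if not path.exists():
        raise AlignmentFormatError(f"no such alignment file: {path}")
    if fmt not in ("fasta", "nexus"):
        raise InvalidArgumentError(f"unsupported alignment format {fmt!r}")
    try:
        mat = dendropy.DnaCharacterMatrix.get(path=str(path), schema=fmt)
    except Exception as exc:  # dendropy raises many parser classes
        raise AlignmentFormatError(f"{path}: cannot parse as {fmt}: {exc}") from exc
    taxa = [t.label for t in mat.taxon_namespace]
    rows = [str(mat[t]).replace(" ", "") for t in mat.taxon_namespace]
    if len(set(taxa)) != len(taxa):
        raise AlignmentFormatError(f"{path}: duplicate taxon labels")
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise AlignmentFormatError(f"{path}: ragged alignment, lengths {sorted(lengths)}")
    n_sites = lengths.pop()
    return Alignment.from_strings(taxa, rows, codon_map_for(n_sites, frame_offset))
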