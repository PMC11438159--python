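"""Motif-based expression metrics: negative cis elements and direct repeats.

Two sequence-level counts complement the codon indices: the number of
matches to a library of negative cis elements (premature poly(A) signals,
instability elements, cryptic splice sites, ...) and the number of maximal
direct repeats.  The default motif library is an editable TSV shipped with
the package; it is a reasonable literature-derived set, not a reproduction
of any particular tool's proprietary library, and per-motif hits are
reported so users can swap in their own.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from .codes import reverse_complement
from .core import CodonSequence

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[GC]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

DEFAULT_MIN_REPEAT_LENGTH = 10
DEFAULT_MIN_REPEAT_COPIES = 2


def iupac_to_regex(pattern: str) -> str:
    try:
        return "".join(IUPAC[b] for b in pattern.upper())
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC base {exc.args[0]!r} in {pattern!r}")


@dataclass(frozen=True)
class Motif:
    name: str
    pattern: str            # IUPAC-degenerate DNA
    category: str = "negative_cis"
    citation: str = ""

    def __post_init__(self):
        if not self.pattern:
            raise ValueError("empty motif pattern")
        iupac_to_regex(self.pattern)  # validate


@dataclass
class MotifLibrary:
    motifs: List[Motif] = field(default_factory=list)
    min_repeat_length: int = DEFAULT_MIN_REPEAT_LENGTH
    min_repeat_copies: int = DEFAULT_MIN_REPEAT_COPIES


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int     # 1-based
    matched: str


@dataclass(frozen=True)
class RepeatHit:
    repeat: str
    starts: Tuple[int, ...]  # 1-based

    @property
    def copies(self) -> int:
        return len(self.starts)


def load_motif_library(path: Optional[Path] = None, **kwargs) -> MotifLibrary:
    """Load a motif TSV (name, IUPAC pattern, category, citation)."""
    if path is None:
        text = (resources.files("rarecodon") / "data" / "negative_cis_motifs.tsv").read_text()
    else:
        text = Path(path).read_text()
    motifs = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        name, pattern = parts[0], parts[1]
        category = parts[2] if len(parts) > 2 else "negative_cis"
        citation = parts[3] if len(parts) > 3 else ""
        motifs.append(Motif(name, pattern, category, citation))
    return MotifLibrary(motifs=motifs, **kwargs)


def count_negative_cis(
    seq: CodonSequence,
    library: Optional[MotifLibrary] = None,
    search_reverse: bool = False,
) -> Tuple[int, List[MotifHit]]:
    """Count (possibly overlapping) motif matches on the coding strand.

    With ``search_reverse`` the reverse complement is scanned too; reverse
    hits report the position of the match's first base on the forward
    strand.
    """
    if library is None:
        library = load_motif_library()
    text = seq.nucleotides
    hits: List[MotifHit] = []
    strands = [(text, False)]
    if search_reverse:
        strands.append((reverse_complement(text), True))
    for strand_text, is_rev in strands:
        n = len(strand_text)
        for motif in library.motifs:
            rx = re.compile("(?=(" + iupac_to_regex(motif.pattern) + "))")
            for m in rx.finditer(strand_text):
                matched = m.group(1)
                start = m.start() + 1
                if is_rev:
                    start = n - (m.start() + len(matched)) + 1
                hits.append(MotifHit(motif.name, start, matched))
    hits.sort(key=lambda h: (h.start, h.motif))
    return len(hits), hits


def _maximal_repeats(text: str, min_len: int, min_copies: int) -> List[RepeatHit]:
    """Enumerate maximal repeated substrings by seed-and-extend.

    A repeat is maximal when its occurrence set cannot all be extended by
    the same character on the left or on the right (sequence boundaries
    count as extension blockers).  Seeds are the ``min_len``-mers occurring
    >= ``min_copies`` times; every longer repeat contains such a seed as a
    prefix, so a rightward breadth-first extension over seeds enumerates
    all of them.  Worst case is quadratic on highly repetitive sequences
    (e.g. homopolymers), which validated coding sequences do not approach.
    """
    n = len(text)
    seeds: Dict[str, List[int]] = {}
    for i in range(n - min_len + 1):
        seeds.setdefault(text[i : i + min_len], []).append(i)
    found: Dict[str, Tuple[int, ...]] = {}
    stack = [(w, tuple(p)) for w, p in seeds.items() if len(p) >= min_copies]
    seen = set(w for w, _ in stack)
    while stack:
        w, positions = stack.pop()
        k = len(w)
        right_chars = {text[p + k] if p + k < n else None for p in positions}
        left_chars = {text[p - 1] if p > 0 else None for p in positions}
        right_maximal = len(right_chars) > 1 or None in right_chars
        left_maximal = len(left_chars) > 1 or None in left_chars
        if right_maximal and left_maximal:
            found[w] = tuple(p + 1 for p in positions)
        # extend right per distinct next character
        for ch in right_chars:
            if ch is None:
                continue
            ext = tuple(p for p in positions if p + k < n and text[p + k] == ch)
            if len(ext) >= min_copies:
                w2 = w + ch
                if w2 not in seen:
                    seen.add(w2)
                    stack.append((w2, ext))
    return [RepeatHit(w, starts) for w, starts in sorted(found.items())]


def count_negative_repeats(
    seq: CodonSequence,
    min_len: int = DEFAULT_MIN_REPEAT_LENGTH,
    min_copies: int = DEFAULT_MIN_REPEAT_COPIES,
) -> Tuple[int, List[RepeatHit]]:
    """Count maximal direct repeats of length >= ``min_len`` occurring
    >= ``min_copies`` times; each distinct repeated substring counts once."""
    repeats = _maximal_repeats(seq.nucleotides, min_len, min_copies)
    return len(repeats), repeats
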