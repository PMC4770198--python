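"""Modality profiles: k-mer count vectors, structure-context count vectors
and the tertiary motif indicating vector.

Three views of one candidate site are produced here:

* **1D** — the viewpoint region of the primary sequence is scanned with a
  sliding window of ``k1`` (default 6) and step 1; each k-mer window that
  overlaps the viewpoint by at least one nucleotide increments its word's
  entry in a count vector over the RNA dictionary (bag-of-words document).
* **2D** — every predicted secondary structure of the site is first
  rewritten as a context string over the 6-letter structural alphabet
  {S, M, H, I, B, E} (stem, multiloop, hairpin loop, internal loop, bulge,
  external) and then scanned the same way with ``k2`` (default 8); counts
  are accumulated over the whole structure ensemble.
* **3D** — the hairpin and internal loops overlapping the viewpoint carry
  JAR3D-style motif scores; every catalog motif scored above the cutoff
  (default 0) by any loop sets one bit of the motif indicating vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np

from .io import LoopScoreRecord, MotifCatalog, SiteRecord, StructureRecord

PRIMARY_ALPHABET = "ACGU"
SECONDARY_ALPHABET = "SMHIBE"

#: flank width (nt) considered around the viewpoint for structure prediction
STRUCTURE_FLANK = 150
#: folding-window length and stride (nt) used to tile the extended region
STRUCTURE_WINDOW = 150
STRUCTURE_STEP = 37


@dataclass(frozen=True)
class RnaDictionary:
    """Ordered universe of RNA words; order fixes count-vector coordinates."""

    modality: str  # "primary" | "secondary"
    k: int
    words: tuple[str, ...]

    def __post_init__(self) -> None:
        alphabet = set(PRIMARY_ALPHABET if self.modality == "primary" else SECONDARY_ALPHABET)
        for w in self.words:
            if len(w) != self.k or set(w) - alphabet:
                raise ValueError(f"word {w!r} inconsistent with {self.modality} k={self.k}")
        if len(set(self.words)) != len(self.words):
            raise ValueError("dictionary words must be distinct")

    @property
    def size(self) -> int:
        return len(self.words)

    def index_of(self, word: str) -> int | None:
        try:
            return self._index.get(word)
        except AttributeError:
            object.__setattr__(self, "_index", {w: i for i, w in enumerate(self.words)})
            return self._index.get(word)


@dataclass
class CountVector:
    """Word-count profile of one document plus its total word count D."""

    counts: np.ndarray
    D: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or (self.counts < 0).any():
            raise ValueError("counts must be a nonnegative vector")
        if int(self.counts.sum()) != self.D:
            raise ValueError(f"D={self.D} != sum of counts {int(self.counts.sum())}")


@dataclass(frozen=True)
class LoopRegion:
    """A hairpin or internal loop from the loop decomposition of a structure.

    Hairpin loops have one interval; internal loops (including one-sided
    bulges, whose second interval is empty) have two.  Intervals are in
    site coordinates, half-open.
    """

    loop_kind: str
    intervals: tuple[tuple[int, int], ...]
    rank: int = 1


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return max(a[0], b[0]) < min(a[1], b[1])


# ---------------------------------------------------------------------------
# secondary-structure context annotation
# ---------------------------------------------------------------------------

def pair_table(dot_bracket: str) -> list[int]:
    """Partner index per position (-1 if unpaired); errors on unbalanced input."""
    table = [-1] * len(dot_bracket)
    stack: list[int] = []
    for i, ch in enumerate(dot_bracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced dot-bracket at position {i}")
            j = stack.pop()
            table[i], table[j] = j, i
        elif ch != ".":
            raise ValueError(f"illegal character {ch!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced dot-bracket: unmatched '(' at {stack[-1]}")
    return table


def _loops(table: list[int]):
    """Yield (closing_pair, branches, unpaired_runs) for every loop closed by
    a base pair.  ``branches`` are the helices branching off inside the loop;
    ``unpaired_runs`` are maximal unpaired intervals inside the loop."""
    for i, j in ((i, table[i]) for i in range(len(table)) if table[i] > i):
        branches: list[tuple[int, int]] = []
        runs: list[tuple[int, int]] = []
        k = i + 1
        run_start = None
        while k < j:
            if table[k] >= 0:
                if run_start is not None:
                    runs.append((run_start, k))
                    run_start = None
                branches.append((k, table[k]))
                k = table[k] + 1
            else:
                if run_start is None:
                    run_start = k
                k += 1
        if run_start is not None:
            runs.append((run_start, j))
        yield (i, j), branches, runs


def annotate_contexts(dot_bracket: str) -> str:
    """Rewrite a dot-bracket string over the 6-letter context alphabet.

    Paired positions become S.  Each unpaired position is classified by the
    loop of the pair-table decomposition it belongs to: hairpin loop -> H,
    two-sided internal loop -> I, one-sided bulge -> B, multiloop (closed
    by three or more helices) -> M, outside every base pair -> E.
    """
    table = pair_table(dot_bracket)
    out = ["E"] * len(dot_bracket)
    for k, partner in enumerate(table):
        if partner >= 0:
            out[k] = "S"
    for _, branches, runs in _loops(table):
        if not branches:
            code = "H"
        elif len(branches) == 1:
            code = "I" if len(runs) == 2 else "B"
        else:
            code = "M"
        for a, b in runs:
            for k in range(a, b):
                out[k] = code
    return "".join(out)


def extract_loops(
    dot_bracket: str,
    viewpoint: tuple[int, int],
    offset: int = 0,
    rank: int = 1,
) -> list[LoopRegion]:
    """Hairpin and internal loops (bulges included) overlapping the viewpoint.

    ``offset`` shifts structure coordinates into site coordinates, for
    structures predicted on a window of the site.  Multiloops and external
    regions are excluded; a loop is kept if any of its unpaired intervals
    overlaps the viewpoint by at least one nucleotide.
    """
    table = pair_table(dot_bracket)
    regions: list[LoopRegion] = []
    for (i, j), branches, runs in _loops(table):
        if len(branches) >= 2 or not runs:
            continue
        if not branches:
            intervals = ((runs[0][0] + offset, runs[0][1] + offset),)
            kind = "hairpin"
        else:
            (bi, bj) = branches[0]
            left = (i + 1 + offset, bi + offset)
            right = (bj + 1 + offset, j + offset)
            intervals = (left, right)
            kind = "internal"
        if any(_overlaps(iv, viewpoint) for iv in intervals):
            regions.append(LoopRegion(kind, intervals, rank=rank))
    return regions


# ---------------------------------------------------------------------------
# window scanning
# ---------------------------------------------------------------------------

def scan_windows(
    record: SiteRecord,
    window_len: int = STRUCTURE_WINDOW,
    step: int = STRUCTURE_STEP,
    flank: int = STRUCTURE_FLANK,
) -> list[tuple[int, int]]:
    """Folding windows tiling the viewpoint extended by ``flank`` nt each way.

    Windows of ``window_len`` advance by ``step`` across the extended
    region (clipped at the sequence bounds); a final window flush with the
    right edge is appended when the stride overshoots.  Sequences shorter
    than ``window_len`` yield a single full-sequence window.
    """
    n = len(record.sequence)
    if n <= window_len:
        return [(0, n)]
    lo = max(0, record.viewpoint[0] - flank)
    hi = min(n, record.viewpoint[1] + flank)
    if hi - lo < window_len:  # widen the short extended region to window size
        lo = max(0, min(lo, hi - window_len))
        hi = min(n, lo + window_len)
    windows = []
    start = lo
    while start + window_len <= hi:
        windows.append((start, start + window_len))
        start += step
    if windows[-1][1] < hi:
        windows.append((hi - window_len, hi))
    return windows


# ---------------------------------------------------------------------------
# dictionaries and count vectors
# ---------------------------------------------------------------------------

def full_dictionary(modality: str, k: int) -> RnaDictionary:
    """All ``|alphabet|**k`` words in lexicographic order."""
    alphabet = PRIMARY_ALPHABET if modality == "primary" else SECONDARY_ALPHABET
    words = tuple("".join(p) for p in product(sorted(alphabet), repeat=k))
    return RnaDictionary(modality=modality, k=k, words=words)


def build_dictionary(
    documents: list[str],
    modality: str,
    k: int,
    mode: str = "full_enumeration",
) -> RnaDictionary:
    """Build the RNA dictionary for one modality.

    ``full_enumeration`` enumerates every possible k-length word;
    ``observed_words`` collects the sorted distinct k-mers occurring in the
    training documents (practical for the 6-letter structural alphabet,
    where full enumeration at k=8 would be ~1.7M words).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode == "full_enumeration":
        return full_dictionary(modality, k)
    if mode != "observed_words":
        raise ValueError(f"unknown mode {mode!r}")
    if not documents:
        raise ValueError("observed_words mode needs a non-empty corpus")
    seen: set[str] = set()
    for doc in documents:
        for s in range(len(doc) - k + 1):
            seen.add(doc[s : s + k])
    return RnaDictionary(modality=modality, k=k, words=tuple(sorted(seen)))


def count_1d(record: SiteRecord, dictionary: RnaDictionary, k: int | None = None) -> CountVector:
    """Count k-mer windows of the primary sequence overlapping the viewpoint.

    Windows containing N are skipped, as are words absent from an
    observed-words dictionary.  D is the number of counted windows.
    """
    if dictionary.modality != "primary":
        raise ValueError("count_1d needs a primary-modality dictionary")
    k = dictionary.k if k is None else k
    if k != dictionary.k:
        raise ValueError("k must match the dictionary word length")
    counts = np.zeros(dictionary.size, dtype=np.int64)
    seq = record.sequence
    if len(seq) < k:
        warnings.warn(f"{record.site_id}: sequence shorter than k={k}; empty count vector")
        return CountVector(counts, 0)
    D = 0
    for s in range(len(seq) - k + 1):
        if not _overlaps((s, s + k), record.viewpoint):
            continue
        word = seq[s : s + k]
        if "N" in word:
            continue
        idx = dictionary.index_of(word)
        if idx is None:
            continue
        counts[idx] += 1
        D += 1
    return CountVector(counts, D)


def count_2d(
    record: SiteRecord,
    structures: list[StructureRecord],
    dictionary: RnaDictionary,
    k: int | None = None,
    aggregate: str = "sum",
) -> CountVector:
    """Count structure-context k-mers over the site's structure ensemble.

    Each predicted structure is annotated into a context string and scanned
    independently; windows overlapping the viewpoint are counted.  With
    ``aggregate="sum"`` occurrences are summed over ensemble members
    (default); ``"union"`` takes the elementwise maximum over members, so a
    word is counted at most as often as in the single structure where it is
    most frequent.
    """
    if dictionary.modality != "secondary":
        raise ValueError("count_2d needs a secondary-modality dictionary")
    k = dictionary.k if k is None else k
    if k != dictionary.k:
        raise ValueError("k must match the dictionary word length")
    if aggregate not in ("sum", "union"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    structures = [s for s in structures if s.site_id == record.site_id]
    if not structures:
        warnings.warn(f"{record.site_id}: no structures; empty 2D count vector")
        return CountVector(np.zeros(dictionary.size, dtype=np.int64), 0)
    per_structure = []
    for struct in structures:
        counts = np.zeros(dictionary.size, dtype=np.int64)
        ctx = annotate_contexts(struct.dot_bracket)
        offset = struct.window[0]
        for s in range(len(ctx) - k + 1):
            if not _overlaps((offset + s, offset + s + k), record.viewpoint):
                continue
            idx = dictionary.index_of(ctx[s : s + k])
            if idx is not None:
                counts[idx] += 1
        per_structure.append(counts)
    if aggregate == "sum":
        total = np.sum(per_structure, axis=0)
    else:
        total = np.max(per_structure, axis=0)
    return CountVector(total, int(total.sum()))


def build_motif_vector(
    loop_scores: list[LoopScoreRecord],
    catalog: MotifCatalog,
    cutoff: float = 0.0,
) -> np.ndarray:
    """Binary motif indicating vector of length ``catalog.size``.

    Bit m is set iff any loop of the site scores motif m strictly above the
    cutoff (default 0, the standard JAR3D acceptance score).  Hairpin block
    first, internal block second.
    """
    bits = np.zeros(catalog.size, dtype=np.int8)
    for rec in loop_scores:
        if rec.score > cutoff:
            bits[catalog.index_of(rec.motif_id)] = 1
    return bits


# ---------------------------------------------------------------------------
# dataset-level encoding
# ---------------------------------------------------------------------------

@dataclass
class EncodedDataset:
    """Stacked modality profiles for a list of sites (row order preserved)."""

    site_ids: list[str]
    counts_1d: np.ndarray  # (n_sites, K1) int
    counts_2d: np.ndarray  # (n_sites, K2) int
    bits_3d: np.ndarray  # (n_sites, catalog size) {0,1}
    dictionary_1d: RnaDictionary
    dictionary_2d: RnaDictionary
    catalog: MotifCatalog

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)


def encode_dataset(
    sites: list[SiteRecord],
    structures: list[StructureRecord],
    loop_scores: list[LoopScoreRecord],
    dictionary_1d: RnaDictionary,
    dictionary_2d: RnaDictionary,
    catalog: MotifCatalog,
    cutoff: float = 0.0,
) -> EncodedDataset:
    """Encode all three modality profiles for every site."""
    struct_by_site: dict[str, list[StructureRecord]] = {}
    for s in structures:
        struct_by_site.setdefault(s.site_id, []).append(s)
    loops_by_site: dict[str, list[LoopScoreRecord]] = {}
    for r in loop_scores:
        loops_by_site.setdefault(r.site_id, []).append(r)
    x1 = np.zeros((len(sites), dictionary_1d.size), dtype=np.int64)
    x2 = np.zeros((len(sites), dictionary_2d.size), dtype=np.int64)
    x3 = np.zeros((len(sites), catalog.size), dtype=np.int8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, site in enumerate(sites):
            x1[i] = count_1d(site, dictionary_1d).counts
            x2[i] = count_2d(site, struct_by_site.get(site.site_id, []), dictionary_2d).counts
            x3[i] = build_motif_vector(loops_by_site.get(site.site_id, []), catalog, cutoff)
    return EncodedDataset(
        site_ids=[s.site_id for s in sites],
        counts_1d=x1,
        counts_2d=x2,
        bits_3d=x3,
        dictionary_1d=dictionary_1d,
        dictionary_2d=dictionary_2d,
        catalog=catalog,
    )
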