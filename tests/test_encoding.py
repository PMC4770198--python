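"""Encoding correctness against independent brute-force oracles."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from rbpdeep.encoding import (
    EncodedDataset,
    LoopRegion,
    RnaDictionary,
    annotate_contexts,
    build_dictionary,
    build_motif_vector,
    count_1d,
    count_2d,
    extract_loops,
    full_dictionary,
    pair_table,
    scan_windows,
)
from rbpdeep.io import LoopScoreRecord, SiteRecord, StructureRecord, toy_catalog

from conftest import random_balanced_dot_bracket


# ---------------------------------------------------------------------------
# independent loop-decomposition oracle (recursive over the pair tree)
# ---------------------------------------------------------------------------

def _oracle_contexts(db: str) -> str:
    """Classify positions by recursive descent over the nesting tree,
    independently of the production pair-table walk."""
    table = pair_table(db)
    out = [""] * len(db)

    def children(lo: int, hi: int) -> list[tuple[int, int]]:
        """Top-level pairs strictly inside [lo, hi)."""
        kids = []
        k = lo
        while k < hi:
            if table[k] > k:
                kids.append((k, table[k]))
                k = table[k] + 1
            else:
                k += 1
        return kids

    def classify(lo: int, hi: int, enclosing: tuple[int, int] | None) -> None:
        kids = children(lo, hi)
        kid_positions = set()
        for a, b in kids:
            kid_positions.update(range(a, b + 1))
        unpaired = [k for k in range(lo, hi) if table[k] < 0 and k not in kid_positions]
        if enclosing is None:
            code = "E"
        else:
            n_helices = len(kids)
            if n_helices == 0:
                code = "H"
            elif n_helices == 1:
                (a, b) = kids[0]
                left = [k for k in unpaired if k < a]
                right = [k for k in unpaired if k > b]
                code = "I" if left and right else "B"
            else:
                code = "M"
        for k in unpaired:
            out[k] = code
        for a, b in kids:
            out[a] = out[b] = "S"
            classify(a + 1, b, (a, b))

    classify(0, len(db), None)
    for k, partner in enumerate(table):
        if partner >= 0:
            out[k] = "S"
    return "".join(out)


@pytest.mark.parametrize(
    "db,expected",
    [
        ("((((...))))", "SSSSHHHSSSS"),
        ("....", "EEEE"),
        ("((..((...))))", "SSBBSSHHHSSSS"),
        ("((.((...))..((...)).))", "SSMSSHHHSSMMSSHHHSSMSS"),
        ("((..((...))..))", "SSIISSHHHSSIISS"),
        ("", ""),
    ],
)
def test_annotate_contexts_known_structures(db, expected):
    assert annotate_contexts(db) == expected


def test_annotate_contexts_matches_recursive_oracle():
    rng = np.random.default_rng(42)
    for _ in range(300):
        db = random_balanced_dot_bracket(rng, int(rng.integers(0, 80)))
        got = annotate_contexts(db)
        assert got == _oracle_contexts(db), db
        # every position classified; S count equals bracket count
        assert len(got) == len(db)
        assert got.count("S") == db.count("(") + db.count(")")
        assert set(got) <= set("SMHIBE")


def test_annotate_contexts_rejects_unbalanced():
    for bad in ["(((...)", ")(", "(((", "..a.."]:
        with pytest.raises(ValueError):
            annotate_contexts(bad)


def test_extract_loops_examples():
    loops = extract_loops("((((...))))", (0, 11))
    assert loops == [LoopRegion("hairpin", ((4, 7),))]
    loops = extract_loops("((..((...))))", (0, 13))
    kinds = {(l.loop_kind, l.intervals) for l in loops}
    assert ("hairpin", ((6, 9),)) in kinds
    assert ("internal", ((2, 4), (11, 11))) in kinds
    # viewpoint disjoint from all loops
    assert extract_loops("((((...))))", (0, 2)) == []


def test_extract_loops_matches_context_classes():
    """Positions inside extracted hairpin/internal loops must be annotated
    H or I/B, and all H/I/B positions overlapping the viewpoint must be
    covered by some extracted loop."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        n = int(rng.integers(10, 70))
        db = random_balanced_dot_bracket(rng, n)
        ctx = annotate_contexts(db)
        vp = (0, n)
        loops = extract_loops(db, vp)
        covered = set()
        for loop in loops:
            for a, b in loop.intervals:
                covered.update(range(a, b))
        expected = {k for k, c in enumerate(ctx) if c in "HIB"}
        assert covered == expected, db


def test_scan_windows_geometry():
    site = SiteRecord("s", "A" * 150, (70, 80))
    assert scan_windows(site) == [(0, 150)]
    site = SiteRecord("s", "A" * 450, (150, 300))
    windows = scan_windows(site)
    assert windows[0] == (0, 150)
    assert all(b - a == 150 for a, b in windows)
    assert windows[1][0] - windows[0][0] == 37
    # flush final window
    assert windows[-1][1] == 450


def test_scan_windows_covers_extended_viewpoint():
    rng = np.random.default_rng(3)
    for _ in range(100):
        n = int(rng.integers(20, 900))
        a = int(rng.integers(0, n))
        b = int(rng.integers(a + 1, n + 1))
        site = SiteRecord("s", "A" * n, (a, b))
        windows = scan_windows(site)
        lo = max(0, a - 150)
        hi = min(n, b + 150)
        covered = set()
        for wa, wb in windows:
            assert 0 <= wa < wb <= n
            covered.update(range(wa, wb))
        assert set(range(lo, hi)) <= covered


def test_build_dictionary_modes():
    d = full_dictionary("primary", 2)
    assert d.size == 16
    assert d.words[0] == "AA" and d.words[-1] == "UU"
    d = build_dictionary(["AAAA"], "primary", 3, mode="observed_words")
    assert d.words == ("AAA",)
    rng = np.random.default_rng(0)
    corpus = ["".join(rng.choice(list("ACGU"), 30)) for _ in range(20)]
    obs = build_dictionary(corpus, "primary", 3, mode="observed_words")
    full = full_dictionary("primary", 3)
    assert set(obs.words) <= set(full.words)
    pooled = Counter()
    for doc in corpus:
        pooled.update(doc[i : i + 3] for i in range(len(doc) - 2))
    assert all(pooled[w] >= 1 for w in obs.words)
    with pytest.raises(ValueError):
        build_dictionary([], "primary", 3, mode="observed_words")


def _oracle_count_1d(site: SiteRecord, dictionary: RnaDictionary):
    k = dictionary.k
    counts = Counter()
    for s in range(len(site.sequence) - k + 1):
        word = site.sequence[s : s + k]
        if max(s, site.viewpoint[0]) >= min(s + k, site.viewpoint[1]):
            continue
        if "N" in word or dictionary.index_of(word) is None:
            continue
        counts[word] += 1
    vec = np.zeros(dictionary.size, dtype=int)
    for w, c in counts.items():
        vec[dictionary.index_of(w)] = c
    return vec


def test_count_1d_examples():
    d = full_dictionary("primary", 6)
    cv = count_1d(SiteRecord("s", "AAAAAAA", (0, 7)), d)
    assert cv.D == 2
    assert cv.counts[d.index_of("AAAAAA")] == 2
    # word containing N skipped
    cv = count_1d(SiteRecord("s", "AAANAAAAAA", (0, 10)), d)
    assert cv.counts.sum() == cv.D == 1  # only the last window is N-free


def test_count_1d_matches_bruteforce():
    rng = np.random.default_rng(12)
    d = full_dictionary("primary", 4)
    for _ in range(200):
        n = int(rng.integers(2, 60))
        seq = "".join(rng.choice(list("ACGUN"), n, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        a = int(rng.integers(0, n))
        b = int(rng.integers(a + 1, n + 1))
        site = SiteRecord("s", seq, (a, b))
        cv = count_1d(site, d)
        oracle = _oracle_count_1d(site, d)
        assert np.array_equal(cv.counts, oracle)
        assert cv.D == oracle.sum()


def test_count_1d_viewpoint_case_invariance():
    """Lowercasing flanks is presentation only: identical count vectors."""
    from rbpdeep.io import parse_viewpoint_fasta, write_viewpoint_fasta

    d = full_dictionary("primary", 4)
    site = SiteRecord("s", "ACGUACGUACGU", (4, 8))
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as tmp:
        path = pathlib.Path(tmp) / "x.fa"
        write_viewpoint_fasta([site], path)
        reparsed = parse_viewpoint_fasta(path)[0]
    assert reparsed.viewpoint == site.viewpoint
    assert np.array_equal(count_1d(site, d).counts, count_1d(reparsed, d).counts)


def _oracle_count_2d(site, structures, dictionary):
    k = dictionary.k
    vec = np.zeros(dictionary.size, dtype=int)
    for struct in structures:
        ctx = annotate_contexts(struct.dot_bracket)
        off = struct.window[0]
        for s in range(len(ctx) - k + 1):
            if max(off + s, site.viewpoint[0]) >= min(off + s + k, site.viewpoint[1]):
                continue
            idx = dictionary.index_of(ctx[s : s + k])
            if idx is not None:
                vec[idx] += 1
    return vec


def test_count_2d_examples():
    d2 = build_dictionary(
        ["SSSSHHHSSSS"], "secondary", 8, mode="observed_words"
    )
    site = SiteRecord("s", "ACGUACGUACG", (0, 11))
    struct = StructureRecord("s", (0, 11), "((((...))))")
    cv = count_2d(site, [struct], d2)
    assert cv.D == 4
    for word in ("SSSSHHHS", "SSSHHHSS", "SSHHHSSS", "SHHHSSSS"):
        assert cv.counts[d2.index_of(word)] == 1
    # duplicated ensemble member doubles every count
    cv2 = count_2d(site, [struct, StructureRecord("s", (0, 11), "((((...))))", rank=2)], d2)
    assert np.array_equal(cv2.counts, 2 * cv.counts)
    # union aggregation collapses the duplicate
    cv3 = count_2d(
        site,
        [struct, StructureRecord("s", (0, 11), "((((...))))", rank=2)],
        d2,
        aggregate="union",
    )
    assert np.array_equal(cv3.counts, cv.counts)


def test_count_2d_matches_bruteforce():
    rng = np.random.default_rng(21)
    for _ in range(60):
        n = int(rng.integers(12, 60))
        a = int(rng.integers(0, n))
        b = int(rng.integers(a + 1, n + 1))
        site = SiteRecord("s", "A" * n, (a, b))
        structures = [
            StructureRecord("s", (0, n), random_balanced_dot_bracket(rng, n), rank=r)
            for r in range(1, int(rng.integers(1, 4)) + 1)
        ]
        docs = [annotate_contexts(s.dot_bracket) for s in structures]
        d2 = build_dictionary(docs, "secondary", 4, mode="observed_words")
        cv = count_2d(site, structures, d2)
        oracle = _oracle_count_2d(site, structures, d2)
        assert np.array_equal(cv.counts, oracle)
        assert cv.D == oracle.sum()


def test_build_motif_vector_rules():
    catalog = toy_catalog()
    recs = [
        LoopScoreRecord("s", "hairpin", ((6, 9),), catalog.hairpin_ids[2], 1.2),
        LoopScoreRecord("s", "internal", ((2, 4), (11, 11)), catalog.internal_ids[0], -0.5),
    ]
    bits = build_motif_vector(recs, catalog)
    assert bits.sum() == 1 and bits[2] == 1
    # all sub-threshold scores -> zero vector
    bits = build_motif_vector(
        [LoopScoreRecord("s", "hairpin", ((1, 2),), catalog.hairpin_ids[0], -1.0)], catalog
    )
    assert bits.sum() == 0


def test_build_motif_vector_monotone_in_cutoff():
    rng = np.random.default_rng(5)
    catalog = toy_catalog()
    ids = catalog.hairpin_ids + catalog.internal_ids
    recs = [
        LoopScoreRecord(
            "s",
            catalog.section_of(m),
            ((0, 3),) if catalog.section_of(m) == "hairpin" else ((0, 2), (5, 7)),
            m,
            float(rng.normal()),
        )
        for m in ids
    ]
    prev = build_motif_vector(recs, catalog, cutoff=-2.0)
    for cutoff in (-1.0, 0.0, 0.5, 2.0):
        cur = build_motif_vector(recs, catalog, cutoff=cutoff)
        assert np.all(cur <= prev)
        prev = cur
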