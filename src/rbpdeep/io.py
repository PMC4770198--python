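"""Readers and writers for the external representations used by the framework.

Formats handled here:

* viewpoint FASTA — one record per candidate site; the experimentally
  identified bound interval (the *viewpoint*) is written in uppercase and
  the flanking context in lowercase.  An optional ``label:bound`` /
  ``label:unbound`` token in the header carries the class label.
* structure TSV — predicted secondary structures, one dot-bracket string
  per (site, window, rank) with an optional free energy in kcal/mol.
* loop-score TSV — per-loop tertiary-motif scores in the style of JAR3D
  output: each row assigns one catalog motif a real-valued score for one
  hairpin or internal loop of a site.
* motif catalog TSV — the ordered list of tertiary motif identifiers that
  defines the coordinates of the motif indicating vector.
* model archive — a single ``.npz`` file with a JSON metadata entry; see
  :func:`save_model` / :func:`load_model`.
* MEME minimal motif format for position-frequency matrices.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations



import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MODEL_FORMAT_VERSION = "1"

_RNA_ALPHABET = set("ACGUN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class CatalogMismatchError(FormatError):
    """Raised when a motif id cannot be resolved against the active catalog."""


@dataclass(frozen=True)
class SiteRecord:
    """One candidate binding site: flanked RNA sequence plus viewpoint.

    The viewpoint is the CLIP-identified bound interval, stored as a
    0-based half-open interval into ``sequence``.  ``label`` is one of
    ``"bound"``, ``"unbound"`` or ``"unknown"``.
    """

    site_id: str
    sequence: str
    viewpoint: tuple[int, int]
    label: str = "unknown"

    def __post_init__(self) -> None:
        start, end = self.viewpoint
        if not self.sequence:
            raise ValueError(f"{self.site_id}: empty sequence")
        if not (0 <= start < end <= len(self.sequence)):
            raise ValueError(
                f"{self.site_id}: viewpoint {self.viewpoint} out of bounds "
                f"for sequence of length {len(self.sequence)}"
            )
        if self.label not in ("bound", "unbound", "unknown"):
            raise ValueError(f"{self.site_id}: bad label {self.label!r}")
        bad = set(self.sequence) - _RNA_ALPHABET
        if bad:
            raise FormatError(
                f"{self.site_id}: characters outside ACGUN alphabet: {sorted(bad)}"
            )


@dataclass(frozen=True)
class StructureRecord:
    """One predicted secondary structure for a window of a site."""

    site_id: str
    window: tuple[int, int]
    dot_bracket: str
    rank: int = 1
    energy: float | None = None

    def __post_init__(self) -> None:
        start, end = self.window
        if end - start != len(self.dot_bracket):
            raise FormatError(
                f"{self.site_id}: window {self.window} length "
                f"{end - start} != structure length {len(self.dot_bracket)}"
            )
        depth = 0
        for ch in self.dot_bracket:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise FormatError(f"{self.site_id}: unbalanced dot-bracket")
            elif ch != ".":
                raise FormatError(
                    f"{self.site_id}: illegal character {ch!r} in dot-bracket"
                )
        if depth != 0:
            raise FormatError(f"{self.site_id}: unbalanced dot-bracket")
        if self.rank < 1:
            raise FormatError(f"{self.site_id}: rank must be >= 1")


@dataclass(frozen=True)
class LoopScoreRecord:
    """JAR3D-style score of one loop of a site against one catalog motif."""

    site_id: str
    loop_kind: str  # "hairpin" | "internal"
    intervals: tuple[tuple[int, int], ...]
    motif_id: str
    score: float

    def __post_init__(self) -> None:
        if self.loop_kind not in ("hairpin", "internal"):
            raise FormatError(f"{self.site_id}: bad loop kind {self.loop_kind!r}")
        n = len(self.intervals)
        if (self.loop_kind == "hairpin" and n != 1) or (
            self.loop_kind == "internal" and n != 2
        ):
            raise FormatError(
                f"{self.site_id}: {self.loop_kind} loop needs "
                f"{1 if self.loop_kind == 'hairpin' else 2} interval(s), got {n}"
            )


@dataclass(frozen=True)
class MotifCatalog:
    """Ordered tertiary-motif identifiers; order defines vector coordinates.

    Hairpin-loop identifiers come first, internal-loop identifiers second,
    so the motif indicating vector is ``[hairpin block | internal block]``.
    """

    hairpin_ids: tuple[str, ...]
    internal_ids: tuple[str, ...]
    version: str = "custom"

    def __post_init__(self) -> None:
        ids = list(self.hairpin_ids) + list(self.internal_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("catalog identifiers must be unique")

    @property
    def size(self) -> int:
        return len(self.hairpin_ids) + len(self.internal_ids)

    def index_of(self, motif_id: str) -> int:
        try:
            return self._index[motif_id]
        except AttributeError:
            index = {m: i for i, m in enumerate(self.hairpin_ids)}
            off = len(self.hairpin_ids)
            index.update({m: off + i for i, m in enumerate(self.internal_ids)})
            object.__setattr__(self, "_index", index)
            return self._index[motif_id]

    def section_of(self, motif_id: str) -> str:
        return "hairpin" if self.index_of(motif_id) < len(self.hairpin_ids) else "internal"

    def __contains__(self, motif_id: str) -> bool:
        try:
            self.index_of(motif_id)
            return True
        except KeyError:
            return False


def reference_catalog() -> MotifCatalog:
    """Synthetic stand-in for the RNA 3D Motif Atlas v1.13 listing.

    The real atlas release contains 253 representative hairpin-loop and
    276 representative internal-loop motifs (529 total).  Its identifier
    list is not redistributed here; this constructor emits synthetic
    placeholder identifiers (``HL_S0001`` ...) with the documented section
    sizes, so vector dimensions and block layout match the real catalog.
    """
    hl = tuple(f"HL_S{i:04d}" for i in range(1, 254))
    il = tuple(f"IL_S{i:04d}" for i in range(1, 277))
    return MotifCatalog(hl, il, version="1.13-synthetic")


def toy_catalog(n_hairpin: int = 8, n_internal: int = 8) -> MotifCatalog:
    """Small synthetic catalog used in tests and examples."""
    hl = tuple(f"HL_T{i:02d}" for i in range(n_hairpin))
    il = tuple(f"IL_T{i:02d}" for i in range(n_internal))
    return MotifCatalog(hl, il, version="toy")


# ---------------------------------------------------------------------------
# viewpoint FASTA
# ---------------------------------------------------------------------------

def parse_viewpoint_fasta(path: str | Path) -> list[SiteRecord]:
    """Parse viewpoint-annotated FASTA into :class:`SiteRecord` objects.

    Uppercase letters mark the viewpoint, lowercase letters the flanks
    (GraphProt convention).  The viewpoint is the smallest interval
    covering every uppercase character.  DNA ``T`` is transparently mapped
    to ``U``.  A header token ``label:bound`` or ``label:unbound`` sets the
    label; otherwise it is ``unknown``.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        bad = set(raw) - set("ACGTUNacgtun")
        if bad:
            raise FormatError(
                f"record {rec.id!r}: characters outside ACGTUN alphabet: {sorted(bad)}"
            )
        upper_pos = [i for i, ch in enumerate(raw) if ch.isupper()]
        if not upper_pos:
            raise FormatError(
                f"record {rec.id!r}: no uppercase (viewpoint) characters"
            )
        label = "unknown"
        for token in rec.description.split():
            if token.startswith("label:"):
                value = token.split(":", 1)[1]
                if value not in ("bound", "unbound"):
                    raise FormatError(
                        f"record {rec.id!r}: bad label token {token!r}"
                    )
                label = value
        seq = raw.upper().replace("T", "U")
        records.append(
            SiteRecord(
                site_id=rec.id,
                sequence=seq,
                viewpoint=(upper_pos[0], upper_pos[-1] + 1),
                label=label,
            )
        )
    return records


def write_viewpoint_fasta(records: Iterable[SiteRecord], path: str | Path) -> None:
    """Write sites as viewpoint FASTA (lowercase flanks, uppercase viewpoint)."""
    seq_records = []
    for r in records:
        start, end = r.viewpoint
        text = r.sequence[:start].lower() + r.sequence[start:end] + r.sequence[end:].lower()
        desc = f"label:{r.label}" if r.label != "unknown" else ""
        seq_records.append(SeqRecord(Seq(text), id=r.site_id, description=desc))
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# structure TSV
# ---------------------------------------------------------------------------

_STRUCT_COLUMNS = ["site_id", "window_start", "window_end", "rank", "energy", "dot_bracket"]


def parse_structure_records(path: str | Path) -> list[StructureRecord]:
    """Parse the structure TSV (site_id, window_start, window_end, rank,
    energy, dot_bracket) into :class:`StructureRecord` objects."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _STRUCT_COLUMNS:
            raise FormatError(
                f"{path}: expected header {_STRUCT_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 fields")
            site_id, ws, we, rank, energy, db = parts
            try:
                rec = StructureRecord(
                    site_id=site_id,
                    window=(int(ws), int(we)),
                    rank=int(rank),
                    energy=None if energy in ("", "NA") else float(energy),
                    dot_bracket=db,
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_structure_records(records: Iterable[StructureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_STRUCT_COLUMNS) + "\n")
        for r in records:
            energy = "NA" if r.energy is None else repr(r.energy)
            fh.write(
                f"{r.site_id}\t{r.window[0]}\t{r.window[1]}\t{r.rank}\t"
                f"{energy}\t{r.dot_bracket}\n"
            )


# ---------------------------------------------------------------------------
# loop-score TSV
# ---------------------------------------------------------------------------

_LOOP_COLUMNS = ["site_id", "loop_kind", "intervals", "motif_id", "score"]


def _format_intervals(intervals: Sequence[tuple[int, int]]) -> str:
    return ",".join(f"{a}-{b}" for a, b in intervals)


def _parse_intervals(text: str) -> tuple[tuple[int, int], ...]:
    out = []
    for part in text.split(","):
        a, b = part.split("-")
        out.append((int(a), int(b)))
    return tuple(out)


def parse_loop_scores(path: str | Path, catalog: MotifCatalog) -> list[LoopScoreRecord]:
    """Parse the loop-score TSV, resolving every motif id against ``catalog``."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _LOOP_COLUMNS:
            raise FormatError(f"{path}: expected header {_LOOP_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            site_id, loop_kind, intervals, motif_id, score = line.split("\t")
            if motif_id not in catalog:
                raise CatalogMismatchError(
                    f"{path}:{lineno}: motif id {motif_id!r} not in catalog "
                    f"{catalog.version!r}"
                )
            if catalog.section_of(motif_id) != loop_kind:
                raise CatalogMismatchError(
                    f"{path}:{lineno}: motif {motif_id!r} is a "
                    f"{catalog.section_of(motif_id)} motif but row says {loop_kind!r}"
                )
            records.append(
                LoopScoreRecord(
                    site_id=site_id,
                    loop_kind=loop_kind,
                    intervals=_parse_intervals(intervals),
                    motif_id=motif_id,
                    score=float(score),
                )
            )
    return records


def write_loop_scores(records: Iterable[LoopScoreRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_LOOP_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.site_id}\t{r.loop_kind}\t{_format_intervals(r.intervals)}\t"
                f"{r.motif_id}\t{r.score!r}\n"
            )


# ---------------------------------------------------------------------------
# motif catalog TSV
# ---------------------------------------------------------------------------

def parse_motif_catalog(path: str | Path, version: str = "custom") -> MotifCatalog:
    """Parse a two-column (section, motif_id) TSV into a catalog."""
    hairpin, internal = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            section, motif_id = line.split("\t")
            if section == "hairpin":
                hairpin.append(motif_id)
            elif section == "internal":
                internal.append(motif_id)
            else:
                raise FormatError(f"{path}:{lineno}: bad section {section!r}")
    return MotifCatalog(tuple(hairpin), tuple(internal), version=version)


def write_motif_catalog(catalog: MotifCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in catalog.hairpin_ids:
            fh.write(f"hairpin\t{m}\n")
        for m in catalog.internal_ids:
            fh.write(f"internal\t{m}\n")


# ---------------------------------------------------------------------------
# model archive
# ---------------------------------------------------------------------------

def save_model(model, path: str | Path) -> None:
    """Serialize a trained :class:`~rbpdeep.dbn.MultimodalDbnModel`.

    The archive is a single ``.npz`` with every weight matrix plus a JSON
    metadata entry holding the format version, dictionaries, catalog,
    architecture and training seed, so scoring is self-contained.
    """
    arrays, meta = model.to_arrays()
    meta["format_version"] = MODEL_FORMAT_VERSION
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path: str | Path):
    """Load a model archive written by :func:`save_model`."""
    from .dbn import MultimodalDbnModel

    try:
        with np.load(path, allow_pickle=False) as data:
            arrays = {k: data[k] for k in data.files}
    except Exception as exc:  # zipfile / npz errors on truncation
        raise FormatError(f"{path}: corrupt or unreadable model archive: {exc}") from exc
    if "__meta__" not in arrays:
        raise FormatError(f"{path}: not a model archive (missing metadata)")
    meta = json.loads(arrays.pop("__meta__").tobytes().decode("utf-8"))
    version = meta.pop("format_version", None)
    if version != MODEL_FORMAT_VERSION:
        raise FormatError(
            f"{path}: model format version {version!r} unsupported "
            f"(this build reads version {MODEL_FORMAT_VERSION!r})"
        )
    return MultimodalDbnModel.from_arrays(arrays, meta)


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def write_meme_pfm(
    pfm: np.ndarray,
    path: str | Path,
    name: str = "motif_1",
    alphabet: str = "ACGU",
    nsites: int = 20,
) -> None:
    """Write a position-frequency matrix (columns = positions, rows sum to 1
    per position) in MEME minimal motif format."""
    pfm = np.asarray(pfm, dtype=float)
    if pfm.ndim != 2 or pfm.shape[1] != len(alphabet):
        raise ValueError(f"PFM must be (positions, {len(alphabet)})")
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write(f"ALPHABET= {alphabet}\n\n")
        fh.write("strands: +\n\n")
        freqs = " ".join(f"{ch} {1.0 / len(alphabet):.4f}" for ch in alphabet)
        fh.write(f"Background letter frequencies\n{freqs}\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alphabet= {len(alphabet)} "
            f"w= {pfm.shape[0]} nsites= {nsites} E= 0\n"
        )
        for row in pfm:
            fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
        fh.write("\n")
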