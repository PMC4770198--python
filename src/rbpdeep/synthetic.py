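"""Seeded synthetic site collections with the statistical structure the
framework assumes, so every stage is testable without external datasets.

Positives ("bound" sites) carry three controllable signals inside their
viewpoint: an implanted sequence k-mer, a hairpin-loop structural context
(a stem-loop with a short bulge, rendered directly as a dot-bracket, is
placed over the viewpoint with configurable probability), and elevated
activation of designated informative tertiary catalog motifs.  Negatives
are implant-free background sites whose viewpoints are repositioned
uniformly (position shuffling), mirroring how unbound sites are derived
from bound ones in CLIP-seq benchmarks.

Structures are generated directly rather than folded thermodynamically:
the tests need controlled context labels, not realistic energetics.
Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .encoding import extract_loops
from .io import (
    LoopScoreRecord,
    MotifCatalog,
    SiteRecord,
    StructureRecord,
    toy_catalog,
)

BASES = "ACGU"


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults define the package's benchmark conditions.

    The default geometry is a 150-nt site with a 30-nt viewpoint and an
    ensemble of three structures per site.  The default signals are the
    pyrimidine-rich 6-mer UCUUCU implanted with probability 0.9, a
    viewpoint-centered hairpin in 70% of positive structures, and two
    informative tertiary motifs (one hairpin, one internal) active with
    probability 0.9 in positives versus 0.05 in negatives over a 5%
    background rate.
    """

    n_pos: int = 500
    n_neg: int = 500
    site_length: int = 150
    viewpoint_width: int = 30
    implant_motif: str = "UCUUCU"
    implant_prob: float = 0.9
    context_bias: float = 0.7
    loop_len: int = 12
    stem_len: int = 5  # base pairs per helix segment (two segments per stem)
    bulge_len: int = 2
    informative_bits: tuple[int, ...] = (1, 9)  # catalog indices
    p_bit_pos: float = 0.9
    p_bit_neg: float = 0.05
    background_bit_prob: float = 0.05
    decoy_score_prob: float = 0.1  # sub-threshold rows exercising the cutoff
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    ensemble_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.implant_prob,
            self.context_bias,
            self.p_bit_pos,
            self.p_bit_neg,
            self.background_bit_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if len(self.implant_motif) > self.viewpoint_width:
            raise ValueError("implanted motif longer than the viewpoint")
        if self.viewpoint_width > self.site_length:
            raise ValueError("viewpoint wider than the site")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")


@dataclass
class SyntheticDataset:
    sites: list[SiteRecord]
    structures: list[StructureRecord]
    loop_scores: list[LoopScoreRecord]
    labels: np.ndarray  # 1 bound / 0 unbound, aligned with sites
    catalog: MotifCatalog
    config: SyntheticConfig


def _hairpin_dot_bracket(length: int, center: int, cfg: SyntheticConfig) -> str:
    """One stem-loop with a one-sided bulge, centered near ``center``."""
    stem = cfg.stem_len
    span = 4 * stem + cfg.bulge_len + cfg.loop_len
    start = int(np.clip(center - span // 2, 0, max(0, length - span)))
    if length < span:
        return "." * length
    motif = (
        "(" * stem
        + "." * cfg.bulge_len
        + "(" * stem
        + "." * cfg.loop_len
        + ")" * (2 * stem)
    )
    return "." * start + motif + "." * (length - start - span)


def _random_sequence(rng: np.random.Generator, cfg: SyntheticConfig) -> str:
    return "".join(rng.choice(list(BASES), size=cfg.site_length, p=cfg.base_composition))


def _make_site(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    site_id: str,
    bound: bool,
) -> tuple[SiteRecord, list[StructureRecord]]:
    seq = list(_random_sequence(rng, cfg))
    vp_start = int(rng.integers(0, cfg.site_length - cfg.viewpoint_width + 1))
    viewpoint = (vp_start, vp_start + cfg.viewpoint_width)
    if bound and rng.random() < cfg.implant_prob:
        pos = int(
            rng.integers(vp_start, vp_start + cfg.viewpoint_width - len(cfg.implant_motif) + 1)
        )
        seq[pos : pos + len(cfg.implant_motif)] = list(cfg.implant_motif)
    site = SiteRecord(
        site_id=site_id,
        sequence="".join(seq),
        viewpoint=viewpoint,
        label="bound" if bound else "unbound",
    )
    structures = []
    vp_center = vp_start + cfg.viewpoint_width // 2
    for rank in range(1, cfg.ensemble_size + 1):
        if bound and rng.random() < cfg.context_bias:
            center = vp_center + int(rng.integers(-3, 4))
        else:
            center = int(rng.integers(0, cfg.site_length))
        structures.append(
            StructureRecord(
                site_id=site_id,
                window=(0, cfg.site_length),
                dot_bracket=_hairpin_dot_bracket(cfg.site_length, center, cfg),
                rank=rank,
                energy=round(float(-rng.uniform(2.0, 20.0)), 2),
            )
        )
    return site, structures


def _loop_scores_for_site(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    site: SiteRecord,
    structures: list[StructureRecord],
    catalog: MotifCatalog,
    bound: bool,
) -> list[LoopScoreRecord]:
    loops_by_kind: dict[str, list] = {"hairpin": [], "internal": []}
    for struct in structures:
        for loop in extract_loops(struct.dot_bracket, site.viewpoint, offset=struct.window[0]):
            loops_by_kind[loop.loop_kind].append(loop)
    records = []
    all_ids = catalog.hairpin_ids + catalog.internal_ids
    for idx, motif_id in enumerate(all_ids):
        if idx in cfg.informative_bits:
            p = cfg.p_bit_pos if bound else cfg.p_bit_neg
        else:
            p = cfg.background_bit_prob
        active = rng.random() < p
        decoy = (not active) and rng.random() < cfg.decoy_score_prob
        if not (active or decoy):
            continue
        kind = catalog.section_of(motif_id)
        candidates = loops_by_kind[kind]
        if not candidates:
            continue
        loop = candidates[int(rng.integers(len(candidates)))]
        score = float(rng.exponential(1.0) + 0.05) if active else float(-rng.exponential(1.0))
        records.append(
            LoopScoreRecord(
                site_id=site.site_id,
                loop_kind=kind,
                intervals=loop.intervals,
                motif_id=motif_id,
                score=round(score, 4),
            )
        )
    return records


def shuffle_negatives(positives: list[SiteRecord], seed: int) -> list[SiteRecord]:
    """Relocate each site's viewpoint uniformly (width preserved), label unbound."""
    rng = np.random.default_rng(seed)
    out = []
    for site in positives:
        width = site.viewpoint[1] - site.viewpoint[0]
        if width > len(site.sequence):
            raise ValueError(f"{site.site_id}: viewpoint wider than sequence")
        start = int(rng.integers(0, len(site.sequence) - width + 1))
        out.append(
            dataclasses.replace(site, viewpoint=(start, start + width), label="unbound")
        )
    return out


def generate_dataset(
    config: SyntheticConfig, catalog: MotifCatalog | None = None
) -> SyntheticDataset:
    """Generate sites, structure ensembles, loop scores and labels.

    Deterministic given ``config.seed``.  Negatives are implant-free
    background sites passed through :func:`shuffle_negatives`.
    """
    catalog = catalog or toy_catalog()
    if max(config.informative_bits, default=-1) >= catalog.size:
        raise ValueError("informative bit index outside the catalog")
    rng = np.random.default_rng(config.seed)
    sites: list[SiteRecord] = []
    structures: list[StructureRecord] = []
    labels: list[int] = []

    pos_sites = []
    for i in range(config.n_pos):
        site, struct = _make_site(rng, config, f"pos_{i:05d}", bound=True)
        pos_sites.append(site)
        structures.extend(struct)
    neg_sites = []
    neg_structs: list[StructureRecord] = []
    for i in range(config.n_neg):
        site, struct = _make_site(rng, config, f"neg_{i:05d}", bound=False)
        neg_sites.append(site)
        neg_structs.extend(struct)
    neg_sites = shuffle_negatives(neg_sites, seed=config.seed + 1)
    structures.extend(neg_structs)

    sites = pos_sites + neg_sites
    labels = [1] * config.n_pos + [0] * config.n_neg
    struct_by_site: dict[str, list[StructureRecord]] = {}
    for s in structures:
        struct_by_site.setdefault(s.site_id, []).append(s)
    loop_scores: list[LoopScoreRecord] = []
    for site, label in zip(sites, labels):
        loop_scores.extend(
            _loop_scores_for_site(
                rng, config, site, struct_by_site[site.site_id], catalog, bound=bool(label)
            )
        )
    return SyntheticDataset(
        sites=sites,
        structures=structures,
        loop_scores=loop_scores,
        labels=np.array(labels, dtype=int),
        catalog=catalog,
        config=config,
    )
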