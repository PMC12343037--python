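"""End-to-end batch search over many query structures.

Each query runs through the same pipeline: parse → enumerate type-compatible
anchor mappings → distance pre-screen → cap → superpose + score each survivor
→ keep the best mapping if it beats the score threshold → compute the
whole-structure similarity metrics with the winning transform.  Per-structure
failures never abort a batch; they are logged with a reason code.  Output is
deterministic: independent of input file order and of the worker count, with
the per-structure RNG for the combination cap derived from the global seed
and the structure id.
"""

from __future__ import annotations

import logging
import zlib
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Optional, Sequence

from . import candidate_search, scoring, similarity_metrics
from .seed_model import SeedSite
from .scoring import ScoredMapping
from .structure_io import StructureParseError, parse_structure

logger = logging.getLogger(__name__)

ReasonCode = Literal[
    "hit", "parse_error", "no_candidates", "no_prescreen_pass", "above_threshold"
]


@dataclass(frozen=True)
class SearchConfig:
    prescreen_tol: float = 3.0  # Å
    max_combinations: int = 2000
    score_threshold: float = 1.0  # Å
    neighbor_window: int = 4
    rng_seed: int = 0
    enforce_seed_order: bool = False
    fit_atoms: Literal["ca", "ca+cb"] = "ca+cb"
    additional_match_radius: float = 2.0  # Å
    score_formula: scoring.ScoreFormula = "mean_over_n"
    metrics_enabled: bool = True
    chain: Optional[str] = None

    def __post_init__(self) -> None:
        if self.prescreen_tol <= 0 or self.score_threshold <= 0:
            raise ValueError("tolerances must be > 0")
        if self.max_combinations < 1:
            raise ValueError("max_combinations must be >= 1")


@dataclass
class SearchHit:
    structure_id: str
    best: ScoredMapping
    structural_mapping_percentage: float = 0.0
    structural_local_similarity: float = 0.0


@dataclass
class SearchOutcome:
    """Per-structure result: the hit (if accepted) plus a reason code."""

    structure_id: str
    reason: ReasonCode
    hit: Optional[SearchHit] = None
    detail: str = ""


def structure_rng_seed(global_seed: int, structure_id: str) -> int:
    """Stable per-structure RNG seed, independent of batch composition."""
    return (global_seed ^ zlib.crc32(structure_id.encode())) & 0x7FFFFFFF


def search_structure(
    query, site: SeedSite, config: SearchConfig = SearchConfig()
) -> SearchOutcome:
    """Run the pipeline on an already-parsed query structure."""
    if len(query.residues) < 3:
        return SearchOutcome(query.id, "parse_error", detail="fewer than 3 residues")
    mappings = candidate_search.enumerate_mappings(
        query, site, enforce_seed_order=config.enforce_seed_order
    )
    if not mappings:
        return SearchOutcome(query.id, "no_candidates")
    mappings = [
        m
        for m in mappings
        if candidate_search.prescreen(m, query, site, tolerance=config.prescreen_tol)
    ]
    if not mappings:
        return SearchOutcome(query.id, "no_prescreen_pass")
    mappings = candidate_search.cap_mappings(
        mappings,
        cap=config.max_combinations,
        rng_seed=structure_rng_seed(config.rng_seed, query.id),
    )
    scored = [
        scoring.score_mapping(
            query,
            site,
            m,
            neighbor_window=config.neighbor_window,
            match_radius=config.additional_match_radius,
            include_cb_in_fit=(config.fit_atoms == "ca+cb"),
            formula=config.score_formula,
        )
        for m in mappings
    ]
    best = scoring.select_best(scored, threshold=config.score_threshold)
    if best is None:
        return SearchOutcome(query.id, "above_threshold")

    hit = SearchHit(structure_id=query.id, best=best)
    if config.metrics_enabled:
        pairing = similarity_metrics.pair_ca(site.seed_structure, query, best.transform)
        hit.structural_mapping_percentage = similarity_metrics.structural_mapping_percentage(
            pairing, query
        )
        hit.structural_local_similarity = similarity_metrics.local_similarity(
            pairing, query
        )
    return SearchOutcome(query.id, "hit", hit=hit)


def search_one(
    query_path: str | Path, site: SeedSite, config: SearchConfig = SearchConfig()
) -> Optional[SearchHit]:
    """Search one structure file; returns the hit or None."""
    return _search_path(str(query_path), site, config).hit


def _search_path(query_path: str, site: SeedSite, config: SearchConfig) -> SearchOutcome:
    try:
        query = parse_structure(query_path, chain=config.chain)
    except StructureParseError as exc:
        logger.warning("skipping %s: %s", query_path, exc)
        return SearchOutcome(Path(query_path).stem, "parse_error", detail=str(exc))
    outcome = search_structure(query, site, config)
    logger.info("%s: %s", outcome.structure_id, outcome.reason)
    return outcome


def search_batch(
    query_paths: Sequence[str | Path],
    site: SeedSite,
    config: SearchConfig = SearchConfig(),
    workers: int = 1,
    fetcher: Optional[Callable[[str], str]] = None,
) -> list[SearchHit]:
    """Search many structures; hits sorted by (score, structure id).

    ``fetcher``, if given, maps each entry of ``query_paths`` (e.g. an
    accession) to a local file path before parsing — the hook point for
    plugging in a URL-template downloader; the core itself never touches the
    network.  Results are identical for any ``workers`` >= 1.
    """
    paths = [str(p) for p in query_paths]
    if fetcher is not None:
        paths = [fetcher(p) for p in paths]
    if workers <= 1:
        outcomes = [_search_path(p, site, config) for p in paths]
    else:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            outcomes = list(
                pool.map(_search_path, paths, [site] * len(paths), [config] * len(paths))
            )
    hits = [o.hit for o in outcomes if o.hit is not None]
    hits.sort(key=lambda h: (h.best.score, h.structure_id))
    return hits


def search_batch_outcomes(
    query_paths: Sequence[str | Path],
    site: SeedSite,
    config: SearchConfig = SearchConfig(),
) -> list[SearchOutcome]:
    """Sequential batch run returning every per-structure outcome with its
    reason code (hit / parse_error / no_candidates / no_prescreen_pass /
    above_threshold)."""
    return [_search_path(str(p), site, config) for p in query_paths]


def url_template_fetcher(
    template: str, target_dir: str | Path, downloader: Callable[[str, Path], None]
) -> Callable[[str], str]:
    """Build a fetcher hook from a URL template with an ``{id}`` placeholder.

    ``downloader(url, dest)`` performs the actual transfer (injected so the
    package itself stays network-free); already-downloaded files are reused.
    """
    target = Path(target_dir)
    target.mkdir(parents=True, exist_ok=True)

    def fetch(accession: str) -> str:
        dest = target / f"{accession}.pdb"
        if not dest.exists():
            downloader(template.format(id=accession), dest)
        return str(dest)

    return fetch
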