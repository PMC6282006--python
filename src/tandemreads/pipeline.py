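"""Orchestration of the three end-to-end analyses.

Each ``run_*`` function chains the library stages, writes its TSV outputs
plus a machine-readable parameter manifest into the output directory, and
returns the main result table. The CLI wraps these functions thinly;
importing and calling them from a script is equally supported.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import io as trio
from .longread import cooccurrence, cooccurrence_table
from .motifs import build_count_matrix, profile_expression
from .profile import (compare_strains, copy_number_table, count_rdna_hits,
                      strain_profile)
from .records import MotifSpec, ReadSetMetadata, SequenceRecord, WindowGrid
from .scan import build_catalog, canonical_unit

log = logging.getLogger("tandemreads")


def _write_manifest(outdir: Path, analysis: str, params: dict) -> None:
    path = outdir / f"{analysis}.manifest.json"
    with open(path, "wt") as fh:
        json.dump({"analysis": analysis, "parameters": params}, fh,
                  indent=2, sort_keys=True, default=str)
        fh.write("\n")


# ------------------------------------------------------------ repeat profile

@dataclass
class StrainInput:
    strain_id: str
    reads: list[str]


@dataclass
class RepeatProfileConfig:
    strains: list[StrainInput]
    reference_strain: str
    outdir: str
    genome_size: int | None = None
    reference_fasta: str | None = None
    rdna_fasta: str | None = None
    unit_range: tuple[int, int] = (1, 75)
    tracked_units: list[str] = field(default_factory=list)
    top_n_units: int = 4
    min_tracked_length: int = 5
    rdna_k: int = 15
    rdna_containment_threshold: float = 0.5
    repeat_length_mode: str = "2L"


def run_repeat_profile(config: RepeatProfileConfig) -> pd.DataFrame:
    """Scan every strain's reads, normalize to copy numbers, and compare
    repeat/rDNA read fractions across strains."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_size = config.genome_size
    if genome_size is None and config.reference_fasta:
        genome_size = trio.genome_size_of(trio.read_sequences(config.reference_fasta))
    if genome_size is None:
        raise ValueError("genome_size must be given or derivable from reference_fasta")
    rdna = None
    if config.rdna_fasta:
        rdna_records = trio.read_sequences(config.rdna_fasta)
        rdna = SequenceRecord(id="rDNA",
                              sequence="".join(r.sequence for r in rdna_records))
    ids = [s.strain_id for s in config.strains]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate strain ids {ids!r}")

    catalogs, rdna_hits = {}, {}
    for strain in config.strains:
        reads = [rec for path in strain.reads
                 for rec in trio.read_sequences(path)]
        if not reads:
            raise ValueError(f"strain {strain.strain_id}: no reads")
        md = ReadSetMetadata(total_reads=len(reads),
                             read_length=max(len(r) for r in reads),
                             genome_size=genome_size)
        catalog = build_catalog(reads, config.unit_range, metadata=md)
        catalogs[strain.strain_id] = catalog
        log.info("strain %s: %d reads, %d catalog units", strain.strain_id,
                 len(reads), len(catalog.entries))
        trio.write_catalog(catalog, outdir / f"catalog_{strain.strain_id}.tsv")
        cn = copy_number_table(catalog, config.repeat_length_mode)
        trio.write_report(cn, outdir / f"copy_number_{strain.strain_id}.tsv")
        rdna_hits[strain.strain_id] = (
            count_rdna_hits(reads, rdna, config.rdna_k,
                            config.rdna_containment_threshold) if rdna else 0)

    tracked = [canonical_unit(u) for u in config.tracked_units]
    if not tracked:
        ref_cat = catalogs[config.reference_strain]
        frame = ref_cat.to_frame()
        frame = frame[frame["unit_length"] >= config.min_tracked_length]
        tracked = frame.head(config.top_n_units)["canonical_unit"].tolist()
    profiles = [strain_profile(catalogs[s.strain_id], rdna_hits[s.strain_id],
                               s.strain_id, tracked)
                for s in config.strains]
    comparison = compare_strains(profiles, config.reference_strain)
    trio.write_report(comparison, outdir / "strain_comparison.tsv")
    _write_manifest(outdir, "repeat_profile", {
        **{k: v for k, v in asdict(config).items()},
        "genome_size_resolved": genome_size,
        "tracked_units_resolved": tracked,
    })
    return comparison


# --------------------------------------------------------------- cooccur

@dataclass
class CooccurConfig:
    long_reads: str
    units: list[str]
    rdna_fasta: str
    outdir: str
    min_hits: int = 3
    k: int = 15
    containment_threshold: float = 0.10


def run_cooccur(config: CooccurConfig) -> pd.DataFrame:
    """Classify long reads and report per-unit repeat/rDNA co-occurrence."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not config.units:
        log.warning("empty unit list: writing empty co-occurrence table")
        table = cooccurrence_table([])
    else:
        reads = trio.read_sequences(config.long_reads)
        rdna_records = trio.read_sequences(config.rdna_fasta)
        rdna = SequenceRecord(id="rDNA",
                              sequence="".join(r.sequence for r in rdna_records))
        results = cooccurrence(reads, config.units, rdna,
                               min_hits=config.min_hits, k=config.k,
                               containment_threshold=config.containment_threshold)
        table = cooccurrence_table(results)
        log.info("classified %d long reads against %d units", len(reads),
                 len(config.units))
    trio.write_report(table, outdir / "cooccurrence.tsv")
    _write_manifest(outdir, "cooccur", asdict(config))
    return table


# ----------------------------------------------------------- motif profile

@dataclass
class MotifProfileConfig:
    genome_fasta: str
    genes: str
    expression: str
    motifs: list[str]
    outdir: str
    extents: tuple[int, ...] = tuple(range(200, 2001, 200))
    cap: int = 2


def run_motif_profile(config: MotifProfileConfig) -> pd.DataFrame:
    """TSS-window motif counts joined to differential expression."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not config.motifs:
        raise ValueError("at least one motif required")
    genome = trio.as_genome_dict(trio.read_sequences(config.genome_fasta))
    genes = trio.read_gene_annotations(config.genes)
    expression = trio.read_expression_table(config.expression)
    grid = WindowGrid(extents=tuple(config.extents))
    frames = []
    for m in config.motifs:
        spec = MotifSpec(motif=m)
        cells = build_count_matrix(genome, genes, spec, grid, config.cap)
        prof = profile_expression(cells, expression, config.cap)
        prof.insert(0, "motif", m)
        frames.append(prof)
    table = pd.concat(frames, ignore_index=True)
    trio.write_report(table, outdir / "motif_profile.tsv")
    _write_manifest(outdir, "motif_profile", asdict(config))
    return table
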