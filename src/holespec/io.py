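"""Readers, writers, run configuration, and the end-to-end pipeline.

Internal coordinates are 1-based inclusive (rCRS convention); exported
BED/bedGraph files use the 0-based half-open dialect, converted at the
boundary and covered by round-trip tests.  Sequence input is FASTA or
GenBank flat file (via Biopython); variant and mutation tables are
delimited text with (position, frequency[, allele, label]) columns,
matching MITOMAP-style allele-search exports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from Bio import SeqIO

from .conservation import conservation_track
from .ladder import BaseSequence, ModelParams, build_duplex, build_hamiltonian
from .peaks import Peak, call_peaks, match_to_features
from .spectrum import (
    DEFAULT_KBT,
    diagonalize,
    hole_spectrum,
    normalize_track,
)
from .variants import (
    CorrelationConfig,
    MutationTrack,
    VariantTrack,
    correlation_pipeline,
    variant_constrain,
)

__all__ = [
    "read_sequence",
    "load_nd1",
    "ND1_START",
    "ND1_END",
    "read_variant_table",
    "read_mutation_table",
    "write_bedgraph",
    "read_bedgraph",
    "write_peaks_bed",
    "write_spectrum_tsv",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

ND1_START, ND1_END = 3307, 4262  # rCRS coordinates of the ND1 gene


# ---------------------------------------------------------------- sequences

def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "genbank" if line.startswith("LOCUS") else "fasta"
    raise ValueError(f"{path}: empty sequence file")


def _gene_range_from_genbank(record, gene: str) -> tuple[int, int]:
    for feat in record.features:
        if feat.type not in ("gene", "CDS"):
            continue
        names = feat.qualifiers.get("gene", []) + feat.qualifiers.get("product", [])
        if any(gene.lower() == n.lower() for n in names):
            return int(feat.location.start) + 1, int(feat.location.end)
    raise ValueError(f"gene {gene!r} not found in GenBank record")


def read_sequence(
    path: str | Path,
    range: tuple[int, int] | None = None,
    gene: str | None = None,
    allow_ambiguous: bool = False,
) -> BaseSequence:
    """Read the reference (L) strand from FASTA or GenBank.

    ``range`` is a 1-based closed interval on the record's own coordinates;
    ``gene`` (GenBank only) resolves a gene/CDS feature name to its range.
    Without either, the whole record is returned starting at coordinate 1.
    """
    path = Path(path)
    fmt = _sniff_format(path)
    record = next(SeqIO.parse(str(path), fmt), None)
    if record is None:
        raise ValueError(f"{path}: no sequence records")
    if gene is not None:
        if fmt != "genbank":
            raise ValueError("gene lookup requires a GenBank file")
        if range is not None:
            raise ValueError("give either a range or a gene name, not both")
        range = _gene_range_from_genbank(record, gene)
    full = BaseSequence(str(record.seq), start=1, strand="L",
                        allow_ambiguous=allow_ambiguous)
    if range is None:
        return full
    lo, hi = range
    if lo > hi:
        raise ValueError(f"range start {lo} exceeds end {hi}")
    return full.subsequence(lo, hi)


def load_nd1() -> BaseSequence:
    """The packaged rCRS ND1 gene region (NC_012920.1:3307-4262, L-strand)."""
    ref = resources.files("holespec").joinpath("data/nd1_rcrs.fasta")
    with resources.as_file(ref) as path:
        seq = read_sequence(path)
    return BaseSequence(seq.bases, start=ND1_START, strand="L")


# ------------------------------------------------------------------ tables

def _parse_table(path: Path, kind: str):
    """Yield (line_number, fields) for non-empty, non-comment lines,
    skipping a single header line when its first field is not numeric."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f for f in line.replace(",", "\t").split("\t") if f != ""]
            if len(fields) == 1:
                fields = line.split()
            rows.append((lineno, fields))
    if rows:
        first = rows[0][1][0]
        try:
            int(first)
        except ValueError:
            rows = rows[1:]  # header
    if not rows:
        warnings.warn(f"{path}: empty {kind} table, track will be all zero")
    return rows


def read_variant_table(path: str | Path) -> dict[int, float]:
    """Per-position summed variant frequencies from a delimited table.

    Columns: position, frequency[, allele, label].  Several rows for one
    site (multiple alleles) are summed; duplicated (position, allele) rows
    are also summed, with a warning.  Use
    :meth:`holespec.variants.VariantTrack.from_counts` to densify onto a
    segment.
    """
    counts: dict[int, float] = {}
    seen: set[tuple[int, str]] = set()
    for lineno, fields in _parse_table(Path(path), "variant"):
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected position and frequency")
        try:
            pos = int(fields[0])
            freq = float(fields[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row {fields!r}") from exc
        if freq < 0:
            raise ValueError(f"{path}:{lineno}: negative frequency {freq}")
        allele = fields[2] if len(fields) > 2 else ""
        if (pos, allele) in seen and allele:
            warnings.warn(f"{path}:{lineno}: duplicate row for {pos} {allele}, summing")
        seen.add((pos, allele))
        counts[pos] = counts.get(pos, 0.0) + freq
    return counts


def read_mutation_table(path: str | Path) -> dict[int, str]:
    """Per-position disease-mutation labels: position, label[, somatic|inherited]."""
    labels: dict[int, str] = {}
    for lineno, fields in _parse_table(Path(path), "mutation"):
        try:
            pos = int(fields[0])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row {fields!r}") from exc
        label = fields[1] if len(fields) > 1 else "mutation"
        if len(fields) > 2:
            label = f"{label}|{fields[2]}"
        labels[pos] = label
    return labels


# ----------------------------------------------------------------- writers

def write_bedgraph(path: str | Path, chrom: str, start: int, values: np.ndarray) -> None:
    """One 1-bp interval per position, 0-based half-open, contiguous."""
    with open(path, "w") as fh:
        for i, v in enumerate(np.asarray(values, dtype=float)):
            p0 = start - 1 + i
            fh.write(f"{chrom}\t{p0}\t{p0 + 1}\t{v:.10g}\n")


def read_bedgraph(path: str | Path) -> tuple[str, int, np.ndarray]:
    """Inverse of :func:`write_bedgraph` for contiguous 1-bp tracks."""
    chroms, starts, vals = [], [], []
    with open(path) as fh:
        for line in fh:
            c, p0, p1, v = line.split("\t")
            chroms.append(c)
            starts.append(int(p0))
            vals.append(float(v))
    if len(set(chroms)) != 1:
        raise ValueError(f"{path}: expected a single chromosome")
    if starts != list(range(starts[0], starts[0] + len(starts))):
        raise ValueError(f"{path}: intervals are not contiguous")
    return chroms[0], starts[0] + 1, np.array(vals)


def write_peaks_bed(path: str | Path, chrom: str, peaks: Sequence[Peak]) -> None:
    """Peaks as BED: score is the height scaled to [0, 1000], order-preserving."""
    hmax = max((p.height for p in peaks), default=1.0)
    with open(path, "w") as fh:
        for p in sorted(peaks, key=lambda q: q.position):
            score = int(round(1000 * p.height / hmax))
            fh.write(f"{chrom}\t{p.position - 1}\t{p.position}\t{p.strand}\t{score}\n")


def write_spectrum_tsv(path: str | Path, spec, tracks: dict[str, np.ndarray]) -> None:
    """Combined per-position table: position, P_L, P_H, then named tracks."""
    names = list(tracks)
    with open(path, "w") as fh:
        fh.write("position\tP_L\tP_H\t" + "\t".join(names) + "\n")
        for i, pos in enumerate(spec.positions):
            row = [f"{spec.P[i, 0]:.10g}", f"{spec.P[i, 1]:.10g}"]
            row += [f"{tracks[n][i]:.10g}" for n in names]
            fh.write(f"{pos}\t" + "\t".join(row) + "\n")


# ---------------------------------------------------------------- pipeline

@dataclass
class RunConfig:
    """Everything a pipeline run needs; defaults follow the model's
    standard parameterization (see ModelParams, DEFAULT_KBT)."""

    sequence: str | None = None          # path; None selects the packaged ND1
    range: tuple[int, int] | None = None
    gene: str | None = None
    chrom: str = "chrM"
    params: ModelParams = field(default_factory=ModelParams)
    kBT: float = DEFAULT_KBT
    peak_min_height: float = 1.0
    include_ends: bool = False
    correlation: CorrelationConfig = field(default_factory=CorrelationConfig)
    variant_table: str | None = None
    mutation_table: str | None = None
    mutation_magnitude: float = 1.0
    alignment: str | None = None         # aligned amino-acid multi-FASTA
    A_values: tuple[float, ...] = (0.0, 1.0, 10.0, 100.0, 1000.0)
    outdir: str = "holespec_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "params" in raw:
            raw["params"] = ModelParams(**raw["params"])
        if "correlation" in raw:
            raw["correlation"] = CorrelationConfig(
                **{k: tuple(v) if k == "subrange" else v
                   for k, v in raw["correlation"].items()}
            )
        for key in ("range", "A_values"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _load_sequence(cfg: RunConfig) -> BaseSequence:
    if cfg.sequence is None:
        seq = load_nd1()
        if cfg.range is not None:
            seq = seq.subsequence(*cfg.range)
        return seq
    return read_sequence(cfg.sequence, range=cfg.range, gene=cfg.gene)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every configured stage and write the artifact bundle.

    Stages: spectrum (always), peaks (always), correlation and variant
    constraint (with a variant table), peak-feature matching (with a
    mutation and/or variant table), conservation (with an alignment).
    Outputs are deterministic for a fixed config, and the JSON manifest
    records every parameter along with headline numbers per stage.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_dict(), "stages": {}, "outputs": {}}

    def _stage(name):
        logger.info("stage %s", name)
        manifest["stages"][name] = "run"

    try:
        _stage("sequence")
        seq = _load_sequence(cfg)
        manifest["stages"]["sequence"] = {
            "start": seq.start, "end": seq.end, "n_sites": len(seq)}

        _stage("spectrum")
        duplex = build_duplex(seq)
        es = diagonalize(build_hamiltonian(duplex, cfg.params))
        spec = hole_spectrum(es, cfg.kBT)
        n_both = normalize_track(spec, "both_strands")
        n_l = normalize_track(spec, "L_only")
        n_h = normalize_track(spec, "H_only")
        manifest["stages"]["spectrum"] = {
            "n_states": es.n_states, "kBT": cfg.kBT,
            "ground_energy_eV": es.ground_energy}
        for label, track, col in (("L", n_both, 0), ("H", n_both, 1)):
            p = out / f"spectrum_{label}.bedGraph"
            write_bedgraph(p, cfg.chrom, spec.start, track.values[:, col])
            manifest["outputs"][f"spectrum_{label}"] = p.name
        tsv = out / "spectrum.tsv"
        write_spectrum_tsv(tsv, spec, {
            "N_L": n_l.strand("L"), "N_H": n_h.strand("H")})
        manifest["outputs"]["spectrum_tsv"] = tsv.name

        _stage("peaks")
        peaks_l = call_peaks(n_l, "L", cfg.peak_min_height, cfg.include_ends)
        peaks_h = call_peaks(n_h, "H", cfg.peak_min_height, cfg.include_ends)
        bed = out / "peaks.bed"
        write_peaks_bed(bed, cfg.chrom, peaks_l + peaks_h)
        manifest["outputs"]["peaks"] = bed.name
        manifest["stages"]["peaks"] = {
            "L": len(peaks_l), "H": len(peaks_h),
            "min_height": cfg.peak_min_height}

        variants = None
        if cfg.variant_table is not None:
            _stage("correlation")
            counts = read_variant_table(cfg.variant_table)
            variants = VariantTrack.from_counts(counts, seq.start, seq.end)
            r = correlation_pipeline(n_l.strand("L"), variants, cfg.correlation)
            r_h = correlation_pipeline(n_h.strand("H"), variants, cfg.correlation)
            rpath = out / "correlation.tsv"
            with open(rpath, "w") as fh:
                fh.write("strand\tconfiguration\tr\n")
                for strand, rr in (("L", r), ("H", r_h)):
                    for name, val in rr.items():
                        fh.write(f"{strand}\t{name}\t{val:.6f}\n")
            manifest["outputs"]["correlation"] = rpath.name
            manifest["stages"]["correlation"] = {"L": r, "H": r_h}

            _stage("constraint")
            for A in cfg.A_values:
                ct = variant_constrain(n_l.strand("L"), variants, A)
                p = out / f"constrained_L_A{A:g}.bedGraph"
                write_bedgraph(p, cfg.chrom, seq.start, ct.values)
                manifest["outputs"][f"constrained_A{A:g}"] = p.name
            manifest["stages"]["constraint"] = {"A_values": list(cfg.A_values)}
        else:
            manifest["stages"]["correlation"] = "skipped: no variant table"
            manifest["stages"]["constraint"] = "skipped: no variant table"

        features = []
        if cfg.mutation_table is not None:
            labels = read_mutation_table(cfg.mutation_table)
            mut = MutationTrack.from_positions(
                labels, seq.start, seq.end, cfg.mutation_magnitude)
            features.extend(mut.positions_present.tolist())
        if variants is not None:
            features.extend((np.flatnonzero(variants.g > 0) + seq.start).tolist())
        if features:
            _stage("matching")
            report = match_to_features(peaks_l, features)
            mpath = out / "match_report.tsv"
            with open(mpath, "w") as fh:
                fh.write("tolerance_bp\tcount\tfraction\n")
                for d in report.tolerances:
                    fh.write(f"{d}\t{report.counts[d]}\t{report.fractions[d]:.4f}\n")
            manifest["outputs"]["match_report"] = mpath.name
            manifest["stages"]["matching"] = {
                str(d): report.counts[d] for d in report.tolerances}
        else:
            manifest["stages"]["matching"] = "skipped: no features"

        if cfg.alignment is not None:
            _stage("conservation")
            seqs = [str(r.seq) for r in SeqIO.parse(cfg.alignment, "fasta")]
            track = conservation_track(seqs, seq.start, seq.end)
            p = out / "conservation.bedGraph"
            write_bedgraph(p, cfg.chrom, seq.start, track.per_nucleotide())
            ctsv = out / "conservation.tsv"
            with open(ctsv, "w") as fh:
                fh.write("codon\tS\tC\n")
                for k in range(track.n_codons):
                    fh.write(f"{k + 1}\t{track.S[k]:.6f}\t{track.C[k]:.6f}\n")
            manifest["outputs"]["conservation"] = p.name
            manifest["outputs"]["conservation_tsv"] = ctsv.name
            manifest["stages"]["conservation"] = {"n_codons": track.n_codons}
        else:
            manifest["stages"]["conservation"] = "skipped: no alignment"
    except Exception as exc:
        stage = next((k for k, v in manifest["stages"].items() if v == "run"), "?")
        logger.error("pipeline aborted in stage %r: %s", stage, exc)
        raise

    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    manifest["outputs"]["manifest"] = mpath.name
    return manifest
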