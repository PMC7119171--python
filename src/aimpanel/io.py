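"""Readers and writers for the delimited frequency/genotype formats and VCF.

Two delimited text formats (tab or comma, auto-detected) are supported:

* frequency tables — header ``SNPID, Chromosome, Ref_Allele, Alt_Allele,
  Pop1_Freq, ..., Popk_Freq`` (an optional ``Position`` column, in base
  pairs 1-based, may follow ``Chromosome``); variants along the rows;
* genotype tables — header ``SampleID, Population, SNP1, ..., SNPk``;
  samples along the rows; genotypes coded 0/1/2 as reference-allele counts,
  missing as empty or ``NA``.

A VCF reader converts per-sample GT calls plus a sample-to-population map
into a frequency table (biallelic records only; half-calls and missing
genotypes are excluded from the denominators).
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, MarkerFrequencyTable, PopulationPanel

__all__ = [
    "read_frequency_table",
    "write_frequency_table",
    "read_genotype_table",
    "write_genotype_table",
    "frequencies_from_vcf",
    "write_scores",
    "read_scores",
]

logger = logging.getLogger(__name__)

_MISSING_CODES = {"", "NA", "NaN", "nan"}


class FormatError(ValueError):
    """Input file violates the expected format."""


def _sniff_delimiter(path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_frequency_table(path, counts=None) -> MarkerFrequencyTable:
    """Parse a per-population reference-allele frequency file.

    Population names are taken from the ``<pop>_Freq`` header columns.
    ``counts`` optionally maps population name to sample count; the default
    is equal weighting (every ``c_j = 1``).
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    required = ["SNPID", "Chromosome", "Ref_Allele", "Alt_Allele"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing mandatory column {col!r}")
    freq_cols = [c for c in df.columns if c.endswith("_Freq")]
    if len(freq_cols) < 2:
        raise FormatError(
            f"{path.name}: need at least two '<pop>_Freq' columns, found {freq_cols}"
        )
    pops = [c[: -len("_Freq")] for c in freq_cols]

    ids = df["SNPID"].tolist()
    dup = df["SNPID"][df["SNPID"].duplicated()].tolist()
    if dup:
        raise FormatError(f"{path.name}: duplicate SNPIDs: {sorted(set(dup))[:5]}")

    freqs = np.full((len(df), len(pops)), np.nan)
    for j, col in enumerate(freq_cols):
        for i, raw in enumerate(df[col]):
            text = "" if raw is None or raw != raw else str(raw).strip()
            if text in _MISSING_CODES:
                continue
            try:
                value = float(text)
            except ValueError:
                raise FormatError(
                    f"{path.name} line {i + 2}: non-numeric frequency {raw!r} "
                    f"in column {col}"
                ) from None
            if not 0.0 <= value <= 1.0:
                raise FormatError(
                    f"{path.name} line {i + 2}: frequency {value} in column "
                    f"{col} is outside [0, 1]"
                )
            freqs[i, j] = value

    positions = None
    if "Position" in df.columns:
        try:
            positions = df["Position"].astype(float).to_numpy()
        except ValueError as exc:
            raise FormatError(f"{path.name}: non-numeric Position: {exc}") from None

    if counts is None:
        count_vec = np.ones(len(pops))
    else:
        unknown = set(counts) - set(pops)
        if unknown:
            raise FormatError(f"counts given for unknown populations: {sorted(unknown)}")
        count_vec = np.array([float(counts.get(p, 1.0)) for p in pops])
    panel = PopulationPanel(tuple(pops), count_vec)
    return MarkerFrequencyTable(
        panel=panel,
        ids=ids,
        freqs=freqs,
        chromosomes=df["Chromosome"].tolist(),
        positions=positions,
        ref_alleles=df["Ref_Allele"].tolist(),
        alt_alleles=df["Alt_Allele"].tolist(),
    )


def write_frequency_table(table: MarkerFrequencyTable, path, sep: str = "\t") -> None:
    table.to_dataframe().to_csv(path, sep=sep, index=False, na_rep="NA")


def read_genotype_table(path) -> GenotypeMatrix:
    """Parse an individual-level genotype file (0/1/2 codes, NA/empty missing)."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    for col in ("SampleID", "Population"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing mandatory column {col!r}")
    marker_ids = [c for c in df.columns if c not in ("SampleID", "Population")]
    if not marker_ids:
        raise FormatError(f"{path.name}: no marker columns found")
    dup = df["SampleID"][df["SampleID"].duplicated()].tolist()
    if dup:
        raise FormatError(f"{path.name}: duplicate sample ids: {sorted(set(dup))[:5]}")

    G = np.full((len(df), len(marker_ids)), np.nan)
    for j, col in enumerate(marker_ids):
        for i, raw in enumerate(df[col]):
            text = str(raw).strip()
            if text in _MISSING_CODES:
                continue
            if text not in ("0", "1", "2"):
                raise FormatError(
                    f"{path.name} line {i + 2}, column {col}: genotype must be "
                    f"0/1/2 or NA, got {raw!r}"
                )
            G[i, j] = float(text)
    return GenotypeMatrix(
        sample_ids=df["SampleID"].tolist(),
        population_labels=df["Population"].tolist(),
        marker_ids=marker_ids,
        G=G,
    )


def write_genotype_table(G: GenotypeMatrix, path, sep: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["SampleID", "Population", *G.marker_ids])
        for i, sid in enumerate(G.sample_ids):
            row = [
                "NA" if not np.isfinite(g) else str(int(g)) for g in G.G[i]
            ]
            writer.writerow([sid, G.population_labels[i], *row])


def frequencies_from_vcf(vcf_path, sample_to_population: dict) -> MarkerFrequencyTable:
    """Per-population reference-allele frequencies from VCF genotype calls.

    Multi-allelic records are skipped with a warning; VCF samples absent
    from the map are excluded. The per-population non-missing sample counts
    (maximum over markers) become the panel counts; per-marker counts are
    retained for LEI.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = vcf.samples
    unmapped = [s for s in samples if s not in sample_to_population]
    if unmapped:
        logger.warning(
            "%d VCF sample(s) absent from the population map, excluded: %s",
            len(unmapped),
            ", ".join(unmapped[:5]),
        )
    pops = list(dict.fromkeys(sample_to_population.values()))
    pop_cols: dict[str, list[int]] = {p: [] for p in pops}
    for i, s in enumerate(samples):
        if s in sample_to_population:
            pop_cols[sample_to_population[s]].append(i)
    empty = [p for p, cols in pop_cols.items() if not cols]
    if empty or len(pops) < 2:
        raise FormatError(
            f"populations with zero usable samples in VCF: {empty}"
            if empty
            else "need at least two populations in the sample map"
        )

    ids, chroms, positions, refs, alts = [], [], [], [], []
    freq_rows, count_rows = [], []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(variant.genotypes)[:, :2]  # (n_samples, 2) allele indices
        row_f, row_c = [], []
        for pop in pops:
            block = gt[pop_cols[pop]]
            full = (block >= 0).all(axis=1)  # -1 encodes missing; drop half-calls
            alleles = block[full].ravel()
            if alleles.size == 0:
                row_f.append(np.nan)
                row_c.append(0.0)
            else:
                row_f.append(float((alleles == 0).sum()) / alleles.size)
                row_c.append(float(full.sum()))
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chroms.append(str(variant.CHROM))
        positions.append(float(variant.POS))
        refs.append(variant.REF)
        alts.append(variant.ALT[0])
        freq_rows.append(row_f)
        count_rows.append(row_c)
    if n_multi:
        logger.warning("skipped %d multi-allelic record(s)", n_multi)
    if not ids:
        raise FormatError(f"no usable biallelic records in {vcf_path}")

    counts = np.asarray(count_rows)
    panel = PopulationPanel(tuple(pops), np.maximum(counts.max(axis=0), 1.0))
    return MarkerFrequencyTable(
        panel=panel,
        ids=ids,
        freqs=np.asarray(freq_rows),
        chromosomes=chroms,
        positions=np.asarray(positions),
        ref_alleles=refs,
        alt_alleles=alts,
        per_marker_counts=counts,
    )


def write_scores(table: pd.DataFrame, path, fmt: str = "tsv") -> None:
    """Write a scored marker table: id, chromosome, [position,] ref allele,
    per-population frequencies, score — rows in descending score order."""
    cols = ["SNPID", "Chromosome"]
    if "Position" in table.columns:
        cols.append("Position")
    cols.append("Ref_Allele")
    cols += [c for c in table.columns if c.endswith("_Freq")]
    cols.append("Score")
    out = table.sort_values("Score", ascending=False, kind="mergesort")[cols]
    sep = {"tsv": "\t", "csv": ","}.get(fmt)
    if sep is None:
        raise ValueError(f"format must be 'tsv' or 'csv', got {fmt!r}")
    out.to_csv(path, sep=sep, index=False, na_rep="NA")


def read_scores(path) -> pd.DataFrame:
    sep = _sniff_delimiter(path)
    return pd.read_csv(path, sep=sep)
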