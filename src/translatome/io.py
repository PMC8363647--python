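"""Readers and writers for the pipeline's file formats.

The canonical tabular dialect is TSV: tab-separated, one header row, '.'
decimal separator, no quoting — chosen so outputs diff bit-exactly between
runs.  Sequences travel as FASTA (one file per transcript region, headers =
gene ids), gene lists as one id per line, label images as plain-text integer
matrices (16-bit single-channel TIFF also accepted on input), merge trees as
Newick.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .preprocess import ArrayExperiment, MValueTable
from .seqfeatures import TranscriptRecord

SEP = "\t"


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep=SEP, index=index)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep=SEP, index_col=index_col)


# --- array experiment -------------------------------------------------------


def write_array_experiment(exp: ArrayExperiment, intensities_path, metadata_path) -> None:
    cols = {}
    for aid in exp.array_ids:
        cols[f"{aid}_red_fg"] = exp.red[aid]
        cols[f"{aid}_green_fg"] = exp.green[aid]
    table = pd.DataFrame(cols, index=exp.red.index)
    table.index.name = "probe"
    write_tsv(table, intensities_path)
    meta = exp.meta.copy()
    meta["dye_swap"] = meta["dye_swap"].astype(int)
    write_tsv(meta, metadata_path)


def read_array_experiment(intensities_path, metadata_path) -> ArrayExperiment:
    table = read_tsv(intensities_path)
    meta = read_tsv(metadata_path)
    meta["dye_swap"] = meta["dye_swap"].astype(bool)
    red_cols = [c for c in table.columns if c.endswith("_red_fg")]
    red = table[red_cols]
    red.columns = [c[: -len("_red_fg")] for c in red_cols]
    green_cols = [c[: -len("_red_fg")] + "_green_fg" for c in red_cols]
    green = table[green_cols]
    green.columns = red.columns
    return ArrayExperiment(red=red, green=green, meta=meta)


# --- M values ---------------------------------------------------------------


def write_m_values(m: MValueTable, values_path, metadata_path=None) -> None:
    write_tsv(m.values, values_path)
    if metadata_path is not None:
        meta = m.meta.copy()
        meta["dye_swap"] = meta["dye_swap"].astype(int)
        write_tsv(meta, metadata_path)


def read_m_values(values_path, metadata_path) -> MValueTable:
    values = read_tsv(values_path)
    meta = read_tsv(metadata_path)
    meta["dye_swap"] = meta["dye_swap"].astype(bool)
    return MValueTable(values=values, meta=meta)


# --- transcripts ------------------------------------------------------------

_REGIONS = ("utr5", "cds", "utr3")


def write_transcripts(records: Sequence[TranscriptRecord], outdir) -> dict[str, Path]:
    """Write one FASTA per region plus a region-length table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for region in _REGIONS:
        path = outdir / f"{region}.fa"
        seqs = [
            SeqRecord(Seq(getattr(r, region)), id=r.gene_id, description="")
            for r in records
            if getattr(r, region)
        ]
        SeqIO.write(seqs, str(path), "fasta")
        paths[region] = path
    regions = pd.DataFrame(
        {
            "gene": [r.gene_id for r in records],
            "utr5_len": [len(r.utr5) for r in records],
            "cds_len": [len(r.cds) for r in records],
            "utr3_len": [len(r.utr3) for r in records],
        }
    ).set_index("gene")
    paths["regions"] = outdir / "regions.tsv"
    write_tsv(regions, paths["regions"])
    return paths


def read_transcripts(utr5_path, cds_path, utr3_path) -> list[TranscriptRecord]:
    """Assemble records from three per-region FASTA files (keyed by gene id)."""
    def _load(path) -> dict[str, str]:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}

    utr5, cds, utr3 = _load(utr5_path), _load(cds_path), _load(utr3_path)
    return [
        TranscriptRecord(g, utr5.get(g, ""), cds[g], utr3.get(g, ""))
        for g in cds
    ]


# --- gene lists and annotation maps ----------------------------------------


def write_gene_list(genes: Iterable[str], path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_annotation_map(annot: Mapping[str, set[str]], path) -> None:
    """gene<TAB>term, one pair per line, sorted for reproducibility."""
    with open(path, "w") as fh:
        for gene in sorted(annot):
            for term in sorted(annot[gene]):
                fh.write(f"{gene}{SEP}{term}\n")


def read_annotation_map(path) -> dict[str, set[str]]:
    annot: dict[str, set[str]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        gene, term = ln.split(SEP)[:2]
        annot.setdefault(gene, set()).add(term)
    return annot


def gaf_to_annotation_map(path) -> dict[str, set[str]]:
    """Extract gene->term pairs from GAF 2.x (columns 2 and 5, 1-based)."""
    annot: dict[str, set[str]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("!"):
            continue
        cols = ln.split(SEP)
        if len(cols) < 5:
            continue
        annot.setdefault(cols[1], set()).add(cols[4])
    return annot


# --- label grids ------------------------------------------------------------


def write_label_grid(grid: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(grid, dtype=int), fmt="%d", delimiter=SEP)


def read_label_grid(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return np.asarray(tifffile.imread(str(path))).astype(np.int64)
    return np.loadtxt(path, dtype=np.int64, delimiter=SEP, ndmin=2)


def write_newick(newick: str, path) -> None:
    Path(path).write_text(newick + ("\n" if not newick.endswith("\n") else ""))


def read_newick(path) -> str:
    return Path(path).read_text().strip()
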