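"""Readers and writers for the plain-text formats the pipeline touches.

Peak files are BED-like TSV with at least six columns::

    chrom  start  end  name  count_air  count_smoke

TSS tables are BED6 (chrom, start, end, gene_id, score, strand) where the
interval marks the transcription start site (start for + strand, end-1 for -).
Expression data is a genes x samples TSV plus a sample-sheet TSV; motifs are
JASPAR-style count matrices; gene sets are GMT.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import ExpressionStudy, GenomicInterval, Peak

log = logging.getLogger("epismoke")

BASES = "ACGT"


def _parse_count(token: str, path, lineno: int) -> float:
    try:
        value: float = int(token)
    except ValueError:
        try:
            value = float(token)
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: cannot parse read count {token!r}"
            ) from None
    if value < 0:
        raise ValueError(f"{path}:{lineno}: negative read count {token!r}")
    return value


def read_peaks(path) -> list[Peak]:
    """Read a BED-like peak file with per-condition read counts."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected >=6 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            try:
                interval = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            x_air = _parse_count(fields[4], path, lineno)
            x_smoke = _parse_count(fields[5], path, lineno)
            peaks.append(Peak(interval, name, x_air, x_smoke))
    if not peaks:
        log.warning("peak file %s is empty", path)
    log.info("read %d peaks from %s", len(peaks), path)
    return peaks


def write_peaks(peaks: list[Peak], path) -> None:
    """Write peaks in the 6-column input dialect (round-trips read_peaks)."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{p.name}\t{p.x_air}\t{p.x_smoke}\n"
            )


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    """Tabulate classified/scored peaks with all statistics columns."""
    return pd.DataFrame(
        {
            "chrom": [p.interval.chrom for p in peaks],
            "start": [p.interval.start for p in peaks],
            "end": [p.interval.end for p in peaks],
            "name": [p.name for p in peaks],
            "x_air": [p.x_air for p in peaks],
            "x_smoke": [p.x_smoke for p in peaks],
            "M": [p.M for p in peaks],
            "A": [p.A for p in peaks],
            "M_norm": [p.m_norm for p in peaks],
            "p_value": [p.p_value for p in peaks],
            "label": [p.label for p in peaks],
            "members": ["+".join(p.members) for p in peaks],
        }
    )


def frame_to_peaks(df: pd.DataFrame) -> list[Peak]:
    peaks = []
    for row in df.itertuples(index=False):
        p = Peak(
            GenomicInterval(row.chrom, int(row.start), int(row.end)),
            row.name,
            float(row.x_air),
            float(row.x_smoke),
        )
        for attr, col in [
            ("M", "M"), ("A", "A"), ("m_norm", "M_norm"),
            ("p_value", "p_value"), ("label", "label"),
        ]:
            if hasattr(row, col):
                setattr(p, attr, getattr(row, col))
        if hasattr(row, "members"):
            p.members = tuple(str(row.members).split("+"))
        peaks.append(p)
    return peaks


def read_tss_table(path) -> pd.DataFrame:
    """Read a BED-like gene/TSS table -> columns chrom, tss, gene_id, strand."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        usecols=range(6),
    )
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise ValueError(
            f"{path}: invalid interval {bad.chrom}:{bad.start}-{bad.end}"
        )
    bad_strand = set(df["strand"]) - {"+", "-", "."}
    if bad_strand:
        raise ValueError(f"{path}: invalid strands {sorted(bad_strand)}")
    tss = np.where(df["strand"] == "-", df["end"] - 1, df["start"])
    out = pd.DataFrame(
        {"chrom": df["chrom"], "tss": tss, "gene_id": df["gene_id"].astype(str),
         "strand": df["strand"]}
    )
    if out["gene_id"].duplicated().any():
        dups = out.loc[out["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"{path}: duplicate gene ids {dups[:5]}")
    log.info("read %d TSS records from %s", len(out), path)
    return out


def read_expression(matrix_path, sheet_path) -> ExpressionStudy:
    """Read an expression matrix TSV and its sample sheet TSV."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if matrix.index.duplicated().any():
        dups = matrix.index[matrix.index.duplicated()].tolist()
        raise ValueError(f"{matrix_path}: duplicate gene ids {dups[:5]}")
    sheet = pd.read_csv(sheet_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in sheet.columns:
        raise ValueError(f"{sheet_path}: missing sample_id column")
    sheet = sheet.set_index("sample_id")
    study = ExpressionStudy(matrix, sheet)
    log.info(
        "read expression study: %d genes x %d samples",
        study.n_genes, study.n_samples,
    )
    return study


def write_expression(study: ExpressionStudy, matrix_path, sheet_path) -> None:
    study.matrix.rename_axis("gene_id").to_csv(matrix_path, sep="\t")
    study.samples.rename_axis("sample_id").to_csv(sheet_path, sep="\t")


def read_pwms(path, pseudocount: float = 0.5) -> list:
    """Read JASPAR-style count matrices into probability PWMs.

    Each record is a ``>name`` header followed by four rows (A, C, G, T) of
    equal length.  Counts are converted to per-column probabilities with the
    given pseudocount added to every cell.
    """
    from .motifs import MotifPWM  # local import avoids a cycle

    records: list[tuple[str, list[list[float]]]] = []
    name, rows = None, []

    def flush():
        if name is None:
            return
        if len(rows) != 4:
            raise ValueError(f"{path}: motif {name!r} has {len(rows)} rows, need 4")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(
                f"{path}: motif {name!r} rows of unequal length {sorted(lengths)}"
            )
        records.append((name, rows))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name, rows = line[1:].split()[0], []
            else:
                # tolerate JASPAR "A [ 1 2 3 ]" decoration
                cleaned = line.replace("[", " ").replace("]", " ")
                tokens = cleaned.split()
                if tokens and tokens[0].upper() in ("A", "C", "G", "T"):
                    tokens = tokens[1:]
                rows.append([float(t) for t in tokens])
    flush()

    pwms = []
    for mot_name, rows in records:
        counts = np.asarray(rows, dtype=float)
        if (counts < 0).any():
            raise ValueError(f"{path}: motif {mot_name!r} has negative counts")
        colsums = counts.sum(axis=0)
        if (colsums == 0).any():
            raise ValueError(
                f"{path}: motif {mot_name!r} has a zero-sum column "
                "before pseudocount"
            )
        probs = (counts + pseudocount) / (colsums + 4 * pseudocount)
        pwms.append(MotifPWM(mot_name, probs))
    log.info("read %d PWMs from %s", len(pwms), path)
    return pwms


def write_pwm_counts(pwms_counts: dict[str, np.ndarray], path) -> None:
    """Write named 4xL count matrices in JASPAR-style text."""
    with open(path, "w") as fh:
        for name, counts in pwms_counts.items():
            fh.write(f">{name}\n")
            for base, row in zip(BASES, np.asarray(counts)):
                fh.write(base + "  " + "  ".join(f"{v:g}" for v in row) + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_gmt(path) -> dict[str, tuple[str, tuple[str, ...]]]:
    """Read a GMT catalog -> {set_id: (description, member genes)}."""
    catalog: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 columns"
                )
            set_id, desc = fields[0], fields[1]
            genes = tuple(g.upper() for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}:{lineno}: empty member list")
            catalog[set_id] = (desc, genes)
    log.info("read %d gene sets from %s", len(catalog), path)
    return catalog


def write_gmt(catalog: dict[str, tuple[str, tuple[str, ...]]], path) -> None:
    with open(path, "w") as fh:
        for set_id, (desc, genes) in catalog.items():
            fh.write("\t".join([set_id, desc, *genes]) + "\n")


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip().upper() for line in fh if line.strip()]


def read_regions(path) -> pd.DataFrame:
    """Read a BED-like region file with >=1 per-sample read-count columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 5:
        raise ValueError(
            f"{path}: region file needs chrom,start,end,name plus >=1 "
            "count column"
        )
    ncounts = df.shape[1] - 4
    df.columns = ["chrom", "start", "end", "name"] + [
        f"count_{i + 1}" for i in range(ncounts)
    ]
    return df


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg
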