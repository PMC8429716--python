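"""Readers and writers for SNV tables, VCF, copy-number segments and
signature matrices, plus coverage-based SNV filters.

Internal coordinates are 0-based half-open; 1-based inclusive positions are
accepted on ingest (VCF, segment tables) and converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import MUTATION_TYPES, SampleData, SignatureMatrix, SnvObservation

logger = logging.getLogger(__name__)

_VALID_BASES = {"A", "C", "G", "T"}


@dataclass
class SnvTableRow:
    """One parsed SNV record before copy-number annotation."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    B: int
    D: int
    mutation_type: Optional[int] = None  # index in [0, 96)
    normal_B: Optional[int] = None
    normal_D: Optional[int] = None
    pop_frequency: Optional[float] = None
    in_cosmic: bool = False

    def __post_init__(self) -> None:
        if self.ref not in _VALID_BASES or self.alt not in _VALID_BASES:
            raise ValueError(f"ref/alt must be single nucleotides: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt are identical")
        if not (0 <= self.B <= self.D):
            raise ValueError(f"need 0 <= B <= D, got B={self.B}, D={self.D}")


@dataclass
class CnSegment:
    """Allele-specific clonal copy-number segment, 0-based half-open."""

    chrom: str
    start: int
    end: int
    major: int
    minor: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty segment: [{self.start}, {self.end})")
        if self.minor > self.major or self.minor < 0:
            raise ValueError("need 0 <= minor <= major")


def _label_to_index(label: str) -> int:
    """Mutation-type label to SBS96 index; purine-centric labels are
    reverse-complemented."""
    if label in MUTATION_TYPES.index_of:
        return MUTATION_TYPES.index_of[label]
    if len(label) == 7 and label[1] == "[" and label[5] == "]":
        return MUTATION_TYPES.index_from_context(label[2], label[4], label[0], label[6])
    raise ValueError(f"unrecognized mutation-type label: {label!r}")


def read_signature_matrix(path) -> SignatureMatrix:
    """Read a tab-separated signature matrix.

    Accepts either orientation (types as rows or as columns); the axis with
    96 entries is taken as the mutation-type axis.  Columns are reordered to
    the canonical SBS96 layout.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 96:
        df = df.T
    elif df.shape[1] != 96:
        raise ValueError(
            f"neither axis of {path} has 96 entries (shape {df.shape})"
        )
    order = [_label_to_index(str(c)) for c in df.columns]
    mu = np.zeros((df.shape[0], 96))
    mu[:, order] = df.to_numpy(dtype=float)
    mu /= mu.sum(axis=1, keepdims=True)
    return SignatureMatrix(names=tuple(str(n) for n in df.index), mu=mu)


def write_signature_matrix(sigs: SignatureMatrix, path) -> None:
    df = pd.DataFrame(
        sigs.mu.T, index=list(MUTATION_TYPES.labels), columns=list(sigs.names)
    )
    df.to_csv(path, sep="\t", index_label="MutationType")


def _context_from_reference(reference, chrom: str, pos: int) -> tuple[str, str]:
    """Flanking bases (5', 3') around a 1-based position from a FASTA."""
    seq = reference[chrom][pos - 2 : pos + 1].seq.upper()
    if len(seq) != 3:
        raise ValueError(f"cannot extract context at {chrom}:{pos}")
    return seq[0], seq[2]


def read_snvs(path, format: str = "tsv", reference=None) -> list[SnvTableRow]:
    """Read SNVs from a TSV table or a VCF.

    TSV columns: chrom, pos, ref, alt, B, D, then optionally mutation_type
    (label), context (3-mer), normal_B, normal_D, pop_frequency, cosmic.
    Indels and multi-allelic records are dropped (counts logged).  When no
    type or context column is present, a pyfaidx FASTA is required.
    """
    if format == "tsv":
        rows, dropped = _read_snvs_tsv(path, reference)
    elif format == "vcf":
        rows, dropped = _read_snvs_vcf(path, reference)
    else:
        raise ValueError("format must be 'tsv' or 'vcf'")
    if dropped:
        logger.info("dropped %d non-SNV or malformed records from %s", dropped, path)
    return rows


def _resolve_type(
    ref: str, alt: str, chrom: str, pos: int, label, context, reference
) -> int:
    if label is not None and not (isinstance(label, float) and np.isnan(label)):
        return _label_to_index(str(label))
    if context is not None and isinstance(context, str) and len(context) == 3:
        return MUTATION_TYPES.index_from_context(ref, alt, context[0], context[2])
    if reference is None:
        raise ValueError(
            "no mutation type or context column; a reference FASTA is required"
        )
    five, three = _context_from_reference(reference, chrom, pos)
    return MUTATION_TYPES.index_from_context(ref, alt, five, three)


def _read_snvs_tsv(path, reference) -> tuple[list[SnvTableRow], int]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "B", "D"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SNV table {path} lacks columns: {sorted(missing)}")
    rows: list[SnvTableRow] = []
    dropped = 0
    for i, rec in enumerate(df.itertuples(index=False)):
        ref, alt = str(rec.ref).upper(), str(rec.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _VALID_BASES or alt not in _VALID_BASES:
            dropped += 1
            continue
        try:
            t = _resolve_type(
                ref, alt, str(rec.chrom), int(rec.pos),
                getattr(rec, "mutation_type", None),
                getattr(rec, "context", None), reference,
            )
            row = SnvTableRow(
                chrom=str(rec.chrom), pos=int(rec.pos), ref=ref, alt=alt,
                B=int(rec.B), D=int(rec.D), mutation_type=t,
                normal_B=_opt_int(getattr(rec, "normal_B", None)),
                normal_D=_opt_int(getattr(rec, "normal_D", None)),
                pop_frequency=_opt_float(getattr(rec, "pop_frequency", None)),
                in_cosmic=bool(getattr(rec, "cosmic", False)),
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {i + 2}: {exc}") from exc
        rows.append(row)
    return rows, dropped


def _opt_int(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return int(v)


def _opt_float(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return float(v)


def _read_snvs_vcf(path, reference) -> tuple[list[SnvTableRow], int]:
    import pysam

    rows: list[SnvTableRow] = []
    dropped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                dropped += 1
                continue
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in _VALID_BASES or alt not in _VALID_BASES:
                dropped += 1
                continue
            B = D = None
            if rec.samples:
                call = rec.samples[0]
                ad = call.get("AD")
                if ad is not None and len(ad) >= 2 and ad[0] is not None:
                    B = int(ad[1])
                    D = int(sum(x for x in ad if x is not None))
                dp = call.get("DP")
                if dp is not None and D is None:
                    D = int(dp)
            if B is None or D is None:
                dropped += 1
                continue
            t = _resolve_type(ref, alt, rec.chrom, rec.pos, None, None, reference)
            rows.append(
                SnvTableRow(
                    chrom=rec.chrom, pos=rec.pos, ref=ref, alt=alt, B=B, D=D,
                    mutation_type=t,
                )
            )
    return rows, dropped


def read_cn_segments(path, one_based: bool = True) -> list[CnSegment]:
    """Read segments from a TSV with columns chrom, start, end, major, minor.

    ``one_based=True`` (default) treats start/end as 1-based inclusive and
    converts; if a ``ccf`` column is present, overlapping events collapse to
    the one with the largest CCF (treated as clonal).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "major", "minor"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"segment table {path} lacks columns: {sorted(missing)}")
    if "ccf" in df.columns:
        df = (
            df.sort_values("ccf", ascending=False)
            .drop_duplicates(subset=["chrom", "start", "end"], keep="first")
        )
    offset = 1 if one_based else 0
    segments = [
        CnSegment(
            chrom=str(r.chrom), start=int(r.start) - offset,
            end=int(r.end) - offset + (1 if one_based else 0),
            major=int(r.major), minor=int(r.minor),
        )
        for r in df.itertuples(index=False)
    ]
    return validate_segments(segments)


def validate_segments(segments: list[CnSegment]) -> list[CnSegment]:
    """Check for overlaps per chromosome; raises listing offenders."""
    by_chrom: dict[str, list[CnSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    offenders = []
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                offenders.append((a, b))
    if offenders:
        raise ValueError(f"overlapping copy-number segments: {offenders}")
    return segments


_SEX_CHROMS = {"X", "Y", "chrX", "chrY"}


def annotate_copy_number(
    rows: list[SnvTableRow],
    segments: list[CnSegment],
    default_normal: int = 2,
    sex: Optional[str] = None,
) -> tuple[list[SnvObservation], dict]:
    """Join SNVs to their covering segment; uncovered SNVs and segments with
    major = 0 are excluded (counts returned).

    X/Y SNVs get normal copy number 1 when ``sex="male"``; without a sex
    flag they keep ``default_normal`` with a warning.
    """
    validate_segments(segments)
    if sex is None and any(r.chrom in _SEX_CHROMS for r in rows):
        logger.warning(
            "X/Y SNVs present but no sex flag given; assuming normal copy "
            "number %d on sex chromosomes", default_normal,
        )
    by_chrom: dict[str, list[CnSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for segs in by_chrom.values():
        segs.sort(key=lambda s: s.start)

    out: list[SnvObservation] = []
    drops = {"no_segment": 0, "zero_major": 0}
    for row in rows:
        pos0 = row.pos - 1
        segs = by_chrom.get(row.chrom, [])
        starts = [s.start for s in segs]
        idx = int(np.searchsorted(starts, pos0, side="right")) - 1
        if not segs or idx < 0 or pos0 >= segs[idx].end:
            drops["no_segment"] += 1
            continue
        seg = segs[idx]
        if seg.major < 1:
            drops["zero_major"] += 1
            continue
        c_normal = default_normal
        if sex == "male" and row.chrom in _SEX_CHROMS:
            c_normal = 1
        out.append(
            SnvObservation(
                B=row.B, D=row.D, T=row.mutation_type,
                C_major=seg.major, C_minor=seg.minor, C_normal=c_normal,
            )
        )
    if drops["no_segment"] or drops["zero_major"]:
        logger.info("copy-number annotation dropped %s", drops)
    return out, drops


def tcga_style_filter(rows: list[SnvTableRow]) -> tuple[list[SnvTableRow], dict]:
    """Coverage and frequency filter for exome-style variant calls.

    Keeps rows with matched-normal depth >= 6 where at most one normal read
    (or normal VAF < 0.01) reports the variant, tumor depth >= 8, and at
    least 3 variant reads or tumor VAF > 0.2.  With population-frequency
    annotations, rows above frequency 0.01 are dropped unless flagged as
    COSMIC.  Missing normal columns skip the normal rules with a warning.
    """
    kept: list[SnvTableRow] = []
    drops = {"normal_coverage": 0, "normal_evidence": 0, "tumor_coverage": 0,
             "tumor_evidence": 0, "pop_frequency": 0}
    warned = False
    for row in rows:
        if row.normal_D is None or row.normal_B is None:
            if not warned:
                logger.warning("normal read counts missing; skipping normal-sample rules")
                warned = True
        else:
            if row.normal_D < 6:
                drops["normal_coverage"] += 1
                continue
            normal_vaf = row.normal_B / row.normal_D
            if not (row.normal_B <= 1 or normal_vaf < 0.01):
                drops["normal_evidence"] += 1
                continue
        if row.D < 8:
            drops["tumor_coverage"] += 1
            continue
        vaf = row.B / row.D
        if not (row.B >= 3 or vaf > 0.2):
            drops["tumor_evidence"] += 1
            continue
        if (
            row.pop_frequency is not None
            and row.pop_frequency > 0.01
            and not row.in_cosmic
        ):
            drops["pop_frequency"] += 1
            continue
        kept.append(row)
    return kept, drops


# ---------------------------------------------------------------------------
# simulator sample round-trip


def write_sample_tsv(sample: SampleData, path) -> None:
    """Write a sample as TSV (one SNV per row, placeholder coordinates)."""
    df = pd.DataFrame(
        {
            "chrom": "sim",
            "mutation_type": [MUTATION_TYPES.labels[t] for t in sample.T],
            "B": sample.B,
            "D": sample.D,
            "C_normal": sample.C_normal,
            "C_major": sample.C_major,
            "C_minor": sample.C_minor,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_sample_tsv(path, purity: float) -> SampleData:
    df = pd.read_csv(path, sep="\t")
    T = np.array([_label_to_index(lab) for lab in df["mutation_type"]])
    return SampleData.from_arrays(
        B=df["B"].to_numpy(), D=df["D"].to_numpy(), T=T,
        C_major=df["C_major"].to_numpy(), C_minor=df["C_minor"].to_numpy(),
        C_normal=df["C_normal"].to_numpy(), purity=purity,
    )
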