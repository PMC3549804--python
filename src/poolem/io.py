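"""Count-table and pileup-text ingestion, and TSV/VCF-style output.

The native interchange format is a tab-separated count table with one row
per locus x pool:

    # poolem-counts v1
    # K <group>=<chromosomes per pool>          (one line per group)
    chrom  pos  ref  alt  pool_id  group  n_major  n_minor

``group`` is "case", "control" or "none".  Pool size K is recorded
explicitly in the header rather than inferred.  Coordinates are 1-based.
On reading, indel rows (multi-base alleles) are dropped, and a locus is
kept only if every pool of its group has at least one read; both filters
log the number of rows removed.

A minimal parser for samtools-mpileup text (one base/quality column set
per pool) produces the same table from real alignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import pandas as pd

from .model import LocusData, PoolCounts

__all__ = ["CountTable", "read_count_table", "write_count_table",
           "counts_from_pileup", "write_calls", "write_vcf"]

logger = logging.getLogger(__name__)

_COLUMNS = ["chrom", "pos", "ref", "alt", "pool_id", "group",
            "n_major", "n_minor"]
_GROUPS = {"case", "control", "none"}


@dataclass
class CountTable:
    """Validated per-locus, per-pool allele counts plus pool-size metadata.

    ``chromosomes_per_pool`` maps group name -> K for that group's pools.
    """

    frame: pd.DataFrame
    chromosomes_per_pool: dict[str, int]

    def loci(self, group: str = "none") -> Iterator[LocusData]:
        """Yield one LocusData per (chrom, pos) for the given group, pools
        ordered by pool_id, in coordinate order."""
        if group not in self.chromosomes_per_pool:
            raise KeyError(f"no K recorded for group {group!r}")
        K = self.chromosomes_per_pool[group]
        sub = self.frame[self.frame["group"] == group]
        for (chrom, pos, ref, alt), rows in sub.groupby(
                ["chrom", "pos", "ref", "alt"], sort=True):
            rows = rows.sort_values("pool_id")
            pools = tuple(PoolCounts(int(r.n_major), int(r.n_minor))
                          for r in rows.itertuples())
            yield LocusData(pools, K, locus_id=(chrom, int(pos), ref, alt))


def _validate_and_filter(frame: pd.DataFrame, K: dict[str, int],
                         strict: bool = True) -> pd.DataFrame:
    if (frame["n_major"] < 0).any() or (frame["n_minor"] < 0).any():
        raise ValueError("negative read counts in count table")
    bad_group = set(frame["group"]) - _GROUPS
    if bad_group:
        raise ValueError(f"unknown group labels {sorted(bad_group)}")
    missing = set(frame["group"]) - set(K)
    if missing:
        raise ValueError(f"missing K metadata for groups {sorted(missing)}")
    dup = frame.duplicated(["chrom", "pos", "group", "pool_id"])
    if dup.any():
        raise ValueError("duplicate (chrom, pos, pool_id) rows in count table")

    is_indel = (frame["ref"].str.len() > 1) | (frame["alt"].str.len() > 1)
    if is_indel.any():
        logger.info("dropping %d indel rows", int(is_indel.sum()))
        frame = frame[~is_indel]

    # A locus is retained only if every pool of its group saw >= 1 read.
    depth = frame["n_major"] + frame["n_minor"]
    min_depth = depth.groupby(
        [frame["chrom"], frame["pos"], frame["group"]]).transform("min")
    uncovered = min_depth == 0
    if uncovered.any():
        n_loci = frame.loc[uncovered, ["chrom", "pos"]].drop_duplicates().shape[0]
        logger.info("dropping %d loci with a zero-coverage pool", n_loci)
        frame = frame[~uncovered]
    return frame.reset_index(drop=True)


def read_count_table(path, strict: bool = True) -> CountTable:
    """Read and validate a poolem count-table TSV.

    Malformed rows raise with their line number; missing K metadata for a
    present group raises.
    """
    K: dict[str, int] = {}
    rows = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("K "):
                    for item in body[2:].split():
                        group, _, value = item.partition("=")
                        try:
                            K[group] = int(value)
                        except ValueError:
                            raise ValueError(
                                f"line {lineno}: bad K metadata {item!r}")
                continue
            fields = line.split("\t")
            if header is None:
                if fields != _COLUMNS:
                    raise ValueError(
                        f"line {lineno}: expected header {_COLUMNS}, got {fields}")
                header = fields
                continue
            if len(fields) != len(_COLUMNS):
                raise ValueError(
                    f"line {lineno}: expected {len(_COLUMNS)} columns, "
                    f"got {len(fields)}")
            try:
                rows.append((fields[0], int(fields[1]), fields[2], fields[3],
                             fields[4], fields[5], int(fields[6]),
                             int(fields[7])))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
    if header is None:
        raise ValueError(f"{path}: no header line found")
    frame = pd.DataFrame(rows, columns=_COLUMNS)
    frame = _validate_and_filter(frame, K, strict=strict)
    return CountTable(frame=frame, chromosomes_per_pool=K)


def write_count_table(table: CountTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("# poolem-counts v1\n")
        if table.chromosomes_per_pool:
            meta = " ".join(f"{g}={k}" for g, k in
                            sorted(table.chromosomes_per_pool.items()))
            fh.write(f"# K {meta}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in table.frame.itertuples(index=False):
            fh.write("\t".join(str(x) for x in r) + "\n")


# --- samtools-mpileup text ingestion -----------------------------------

def _parse_bases(bases: str, quals: str, ref: str, min_quality: int):
    """Walk one pileup base string, pairing base-consuming symbols with
    quality characters, and return filtered base calls (uppercase)."""
    calls = []
    qi = 0
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":          # read start; next char is mapping quality
            i += 2
            continue
        if c == "$":          # read end marker, no quality
            i += 1
            continue
        if c in "+-":         # indel: +NNseq / -NNseq, no quality
            i += 1
            num = ""
            while i < n and bases[i].isdigit():
                num += bases[i]
                i += 1
            i += int(num)
            continue
        # base-consuming symbols: . , ACGTacgt N n * and > <
        if qi >= len(quals):
            raise ValueError("base/quality strings out of sync")
        q = ord(quals[qi]) - 33
        qi += 1
        i += 1
        if c in ".,":
            base = ref.upper()
        elif c.upper() in "ACGT":
            base = c.upper()
        else:                 # deletion placeholder or reference skip
            continue
        if q >= min_quality:
            calls.append(base)
    return calls


def counts_from_pileup(path, chromosomes_per_pool: int,
                       min_base_quality: int = 20,
                       group: str = "none") -> CountTable:
    """Build a CountTable from samtools-mpileup-style text.

    Each line is ``chrom pos ref`` followed by one (depth, bases, quals)
    column triplet per pool.  Per pool, reference-matching bases count as
    major and the locus-wide most frequent alternative base as minor;
    further alternative bases are dropped with a log message.  Bases
    below ``min_base_quality`` are discarded.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6 or (len(fields) - 3) % 3:
                raise ValueError(
                    f"line {lineno}: expected 3 + 3*pools columns, "
                    f"got {len(fields)}")
            chrom, pos, ref = fields[0], fields[1], fields[2]
            try:
                pos = int(pos)
            except ValueError:
                raise ValueError(f"line {lineno}: bad position {fields[1]!r}")
            per_pool = []
            alt_tally: dict[str, int] = {}
            for p in range(3, len(fields), 3):
                try:
                    calls = _parse_bases(fields[p + 1], fields[p + 2], ref,
                                         min_base_quality)
                except ValueError as exc:
                    raise ValueError(f"line {lineno}: {exc}") from None
                per_pool.append(calls)
                for b in calls:
                    if b != ref.upper():
                        alt_tally[b] = alt_tally.get(b, 0) + 1
            if alt_tally:
                alt = max(sorted(alt_tally), key=alt_tally.get)
                if len(alt_tally) > 1:
                    logger.info("line %d: keeping alternative %s, dropping %s",
                                lineno, alt,
                                sorted(set(alt_tally) - {alt}))
            else:
                alt = "N"
            for pool_idx, calls in enumerate(per_pool):
                n_major = sum(b == ref.upper() for b in calls)
                n_minor = sum(b == alt for b in calls)
                rows.append((chrom, pos, ref.upper(), alt,
                             f"pool{pool_idx + 1}", group, n_major, n_minor))
    frame = pd.DataFrame(rows, columns=_COLUMNS)
    K = {group: chromosomes_per_pool}
    frame = _validate_and_filter(frame, K)
    return CountTable(frame=frame, chromosomes_per_pool=K)


# --- result writers -----------------------------------------------------

def write_calls(results, path) -> None:
    """Ranked call results as TSV: locus, frequencies, alpha, Lambda, p, rank."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tf_control\tf_case\talpha\t"
                 "lrt_statistic\tp_value\trank\n")
        for r in results:
            chrom, pos, ref, alt = _locus_fields(r.locus_id)
            alt_fit = r.alt_fit
            if hasattr(alt_fit, "f_case"):
                f0, f1, a = alt_fit.f_control, alt_fit.f_case, alt_fit.alpha
            else:
                f0 = f1 = alt_fit.params.f
                a = alt_fit.params.alpha
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{f0:.6g}\t{f1:.6g}\t"
                     f"{a:.6g}\t{r.lrt_statistic:.6g}\t{r.p_value:.6g}\t"
                     f"{r.rank}\n")


def write_vcf(results, path) -> None:
    """Minimal VCF-style output with AF/LRT/P INFO tags."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=poolem\n")
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,'
                 'Description="EM minor allele frequency">\n')
        fh.write('##INFO=<ID=LRT,Number=1,Type=Float,'
                 'Description="Likelihood ratio statistic">\n')
        fh.write('##INFO=<ID=P,Number=1,Type=Float,Description="P-value">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in results:
            chrom, pos, ref, alt = _locus_fields(r.locus_id)
            alt_fit = r.alt_fit
            af = (alt_fit.f_control if hasattr(alt_fit, "f_control")
                  else alt_fit.params.f)
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t"
                     f"AF={af:.6g};LRT={r.lrt_statistic:.6g};"
                     f"P={r.p_value:.6g}\n")


def _locus_fields(locus_id):
    if isinstance(locus_id, tuple) and len(locus_id) == 4:
        return locus_id
    return (str(locus_id), 0, "N", "N")
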