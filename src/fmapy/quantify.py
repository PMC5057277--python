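"""KO abundance per sample: raw counts and protein-length RPKM.

RPKM of a KO g is computed per read from the read's own best-hit protein
length, in amino acids, converted to nucleotides by a factor of 3:

    RPKM(g) = sum_{r in R(g)} 1 / (PL(r) * 3) * (1 / T) * 1e9

where R(g) is the set of reads assigned to g, PL(r) the effective protein
length of read r, and T the total number of mapped (assigned) reads in the
sample. When every best-hit protein shares one length L, this reduces to
raw_count(g) * 1e9 / (3 * L * T), i.e. ordinary RPKM with gene length 3L.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from fmapy.alignment_filter import ReadAssignment

RPKM_SCALE = 1e9
TSV_DECIMALS = 3  # printed precision of RPKM in TSV outputs; storage is double


@dataclass
class SampleAbundance:
    """Per-sample KO abundance: raw counts, RPKM, and the mapped-read total T."""

    sample_id: str
    ko_raw_count: dict[str, int]
    ko_rpkm: dict[str, float]
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if sum(self.ko_raw_count.values()) != self.total_mapped_reads:
            raise ValueError(
                f"sample {self.sample_id!r}: raw counts sum to "
                f"{sum(self.ko_raw_count.values())}, expected "
                f"T = {self.total_mapped_reads}"
            )
        if set(self.ko_rpkm) != set(self.ko_raw_count):
            raise ValueError(
                f"sample {self.sample_id!r}: rpkm and raw-count KO sets differ"
            )


@dataclass
class AbundanceTable:
    """KO x sample abundance matrix (raw and RPKM), plus per-sample totals."""

    kos: list[str]
    samples: list[str]
    raw: pd.DataFrame = field(repr=False)
    rpkm: pd.DataFrame = field(repr=False)
    totals: dict[str, int] = field(default_factory=dict)


def count_raw(assignments: Iterable[ReadAssignment]) -> dict[str, int]:
    """Number of reads mapping to each KO; zero-read KOs are absent."""
    return dict(Counter(a.ko_id for a in assignments))


def compute_rpkm(
    assignments: Sequence[ReadAssignment], total_mapped_reads: int
) -> dict[str, float]:
    """Protein-length RPKM per KO, accumulated read-by-read in input order.

    ``total_mapped_reads`` must equal the number of assignments — T counts
    exactly the reads with a passing best-hit assignment.
    """
    assignments = list(assignments)
    if total_mapped_reads != len(assignments):
        raise ValueError(
            f"total_mapped_reads = {total_mapped_reads} does not match the "
            f"number of assignments ({len(assignments)})"
        )
    if not assignments:
        return {}
    if total_mapped_reads == 0:
        raise ValueError("total_mapped_reads is 0 with nonempty assignments")
    rpkm: dict[str, float] = {}
    inv_t = 1.0 / total_mapped_reads
    for a in assignments:
        contrib = 1.0 / (a.effective_protein_length_aa * 3) * inv_t * RPKM_SCALE
        rpkm[a.ko_id] = rpkm.get(a.ko_id, 0.0) + contrib
    return rpkm


def quantify_sample(
    sample_id: str, assignments: Sequence[ReadAssignment]
) -> SampleAbundance:
    """Raw counts and RPKM for one sample's assignments."""
    assignments = list(assignments)
    t = len(assignments)
    return SampleAbundance(
        sample_id=sample_id,
        ko_raw_count=count_raw(assignments),
        ko_rpkm=compute_rpkm(assignments, t),
        total_mapped_reads=t,
    )


def merge_samples(per_sample: Sequence[SampleAbundance]) -> AbundanceTable:
    """Merge per-sample abundances into one KO x sample table.

    The KO axis is the lexicographically sorted union across samples with
    missing entries filled as zero; sample order is preserved as given.
    """
    sample_ids = [s.sample_id for s in per_sample]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = [s for s, n in Counter(sample_ids).items() if n > 1]
        raise ValueError(f"duplicate sample id(s): {dupes}")
    kos = sorted(set().union(*[s.ko_raw_count.keys() for s in per_sample]))
    raw = pd.DataFrame(0, index=kos, columns=sample_ids, dtype=np.int64)
    rpkm = pd.DataFrame(0.0, index=kos, columns=sample_ids, dtype=np.float64)
    for s in per_sample:
        raw.loc[list(s.ko_raw_count), s.sample_id] = list(s.ko_raw_count.values())
        rpkm.loc[list(s.ko_rpkm), s.sample_id] = list(s.ko_rpkm.values())
    return AbundanceTable(
        kos=kos,
        samples=sample_ids,
        raw=raw,
        rpkm=rpkm,
        totals={s.sample_id: s.total_mapped_reads for s in per_sample},
    )


def write_sample_abundance(sample: SampleAbundance, out_path: Path | str) -> None:
    with open(out_path, "w") as fh:
        fh.write(f"#total_mapped_reads={sample.total_mapped_reads}\n")
        fh.write("ko_id\traw_count\trpkm\n")
        for ko in sorted(sample.ko_raw_count):
            fh.write(
                f"{ko}\t{sample.ko_raw_count[ko]}\t"
                f"{sample.ko_rpkm[ko]:.{TSV_DECIMALS}f}\n"
            )


def read_sample_abundance(path: Path | str, sample_id: str | None = None) -> SampleAbundance:
    path = Path(path)
    total = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#total_mapped_reads="):
                total = int(line.strip().split("=", 1)[1])
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    if total is None:
        raise ValueError(f"{path}: missing '#total_mapped_reads=' comment line")
    return SampleAbundance(
        sample_id=sample_id or path.stem.removesuffix(".abund"),
        ko_raw_count=dict(zip(df["ko_id"], df["raw_count"].astype(int))),
        ko_rpkm=dict(zip(df["ko_id"], df["rpkm"].astype(float))),
        total_mapped_reads=total,
    )


def write_table(
    table: AbundanceTable, out_path: Path | str, metric: str = "rpkm"
) -> None:
    """Write the merged matrix (one column per sample) as TSV."""
    mat = {"rpkm": table.rpkm, "raw": table.raw}[metric]
    out = mat.copy()
    if metric == "rpkm":
        out = out.round(TSV_DECIMALS)
    out.index.name = "ko_id"
    out.to_csv(out_path, sep="\t")


def read_table(path: Path | str, metric: str = "rpkm") -> AbundanceTable:
    """Load a merged matrix TSV back into an AbundanceTable.

    Only the requested metric is populated; the other matrix is filled with
    zeros and totals are reconstructed from raw column sums when available.
    """
    df = pd.read_csv(path, sep="\t", index_col="ko_id")
    zeros = pd.DataFrame(0.0, index=df.index, columns=df.columns)
    raw = df.astype(np.int64) if metric == "raw" else zeros.astype(np.int64)
    rpkm = df.astype(float) if metric == "rpkm" else zeros
    return AbundanceTable(
        kos=list(df.index),
        samples=list(df.columns),
        raw=raw,
        rpkm=rpkm,
        totals=dict(raw.sum(axis=0)) if metric == "raw" else {},
    )
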