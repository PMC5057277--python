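"""Parse protein-alignment tabular output, filter hits, resolve best-hit KOs.

Input is the 12-column tab-separated report shared by BLAST, DIAMOND and
USEARCH-compatible tools ("outfmt 6"):

    qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore

Filtering keeps hits with e-value < 1e-3 and percent identity > 80 by
default; both comparisons are strict, so boundary values are excluded. Each
read is then resolved to a single best hit: the top tier is all hits tied on
(max bitscore, then min e-value), and the effective protein length PL(r) is
the minimum protein length within that tier — the KO is taken from that
minimum-length protein, with lexicographic protein_id as the final
tie-break so output never depends on file order.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from fmapy.refdb import ReferenceDB

logger = logging.getLogger(__name__)

DEFAULT_EVALUE_MAX = 1e-3
DEFAULT_IDENTITY_MIN = 80.0


class ParseError(ValueError):
    """A malformed alignment line, with the line number."""


@dataclass(frozen=True)
class AlignmentHit:
    """One read-vs-protein local alignment record (outfmt-6 fields)."""

    read_id: str
    protein_id: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class ReadAssignment:
    """A read resolved to its best-hit KO.

    effective_protein_length_aa is PL(r): the minimum protein length among
    the read's tied best hits, used as the gene length in the RPKM formula.
    """

    read_id: str
    ko_id: str
    effective_protein_length_aa: int
    winning_protein_id: str


def _open_maybe_gzip(path: Path | str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_tabular(source: Iterable[str] | Path | str) -> Iterator[AlignmentHit]:
    """Yield AlignmentHit records from an outfmt-6 stream or file path.

    '#'-prefixed comment lines and blank lines are skipped; extra trailing
    columns beyond the canonical 12 are ignored. Raises ParseError naming
    the offending line on short or unparseable rows.
    """
    if isinstance(source, (str, Path)):
        with _open_maybe_gzip(source) as fh:
            yield from parse_tabular(fh)
        return
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ParseError(
                f"line {lineno}: expected >= 12 tab-separated fields, "
                f"got {len(fields)}"
            )
        try:
            yield AlignmentHit(
                read_id=fields[0],
                protein_id=fields[1],
                percent_identity=float(fields[2]),
                align_length=int(fields[3]),
                mismatches=int(fields[4]),
                gap_opens=int(fields[5]),
                q_start=int(fields[6]),
                q_end=int(fields[7]),
                s_start=int(fields[8]),
                s_end=int(fields[9]),
                evalue=float(fields[10]),
                bitscore=float(fields[11]),
            )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None


def apply_thresholds(
    hits: Iterable[AlignmentHit],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    identity_min: float = DEFAULT_IDENTITY_MIN,
) -> Iterator[AlignmentHit]:
    """Keep hits with evalue < evalue_max AND percent_identity > identity_min.

    Both inequalities are strict; a hit at exactly the e-value cutoff or
    exactly the identity cutoff is removed.
    """
    for hit in hits:
        if hit.evalue < evalue_max and hit.percent_identity > identity_min:
            yield hit


def select_best_hits(
    hits: Iterable[AlignmentHit], db: ReferenceDB
) -> list[ReadAssignment]:
    """Resolve each read to one best-hit KO with its effective protein length.

    The best-hit tier is every hit tied on (max bitscore, then min e-value).
    PL(r) is the minimum protein length in the tier; the KO and winning
    protein come from that minimum-length member, breaking remaining ties by
    lexicographic protein_id. Hits to proteins absent from the reference are
    dropped (counted in the log) and never contribute to the mapped-read
    total. Input may arrive in any order; one accumulation pass per read is
    used, so memory is proportional to reads, not hits.
    """
    # per read: (best bitscore, best evalue at that bitscore, candidate hits)
    best: dict[str, tuple[float, float, list[AlignmentHit]]] = {}
    n_unknown = 0
    for hit in hits:
        if hit.protein_id not in db.proteins:
            n_unknown += 1
            continue
        entry = best.get(hit.read_id)
        if entry is None:
            best[hit.read_id] = (hit.bitscore, hit.evalue, [hit])
            continue
        score, ev, tier = entry
        if hit.bitscore > score or (hit.bitscore == score and hit.evalue < ev):
            best[hit.read_id] = (hit.bitscore, hit.evalue, [hit])
        elif hit.bitscore == score and hit.evalue == ev:
            tier.append(hit)
    if n_unknown:
        logger.info(
            "select_best_hits: dropped %d hit(s) to unknown subjects", n_unknown
        )
    assignments = []
    for read_id in best:
        _, _, tier = best[read_id]
        winner = min(
            tier, key=lambda h: (db.proteins[h.protein_id].length_aa, h.protein_id)
        )
        prot = db.proteins[winner.protein_id]
        assignments.append(
            ReadAssignment(
                read_id=read_id,
                ko_id=prot.ko_id,
                effective_protein_length_aa=prot.length_aa,
                winning_protein_id=prot.protein_id,
            )
        )
    return assignments


def filter_file(
    alignment_path: Path | str,
    db: ReferenceDB,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    identity_min: float = DEFAULT_IDENTITY_MIN,
) -> list[ReadAssignment]:
    """parse -> threshold -> best-hit for one per-sample alignment file."""
    hits = parse_tabular(alignment_path)
    surviving = apply_thresholds(hits, evalue_max=evalue_max, identity_min=identity_min)
    return select_best_hits(surviving, db)


def write_assignments(
    assignments: Iterable[ReadAssignment], out_path: Path | str
) -> None:
    with open(out_path, "w") as fh:
        fh.write("read_id\tko_id\tprotein_id\tprotein_length_aa\n")
        for a in assignments:
            fh.write(
                f"{a.read_id}\t{a.ko_id}\t{a.winning_protein_id}\t"
                f"{a.effective_protein_length_aa}\n"
            )


def read_assignments(path: Path | str) -> list[ReadAssignment]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ParseError(f"{path}: missing assignment header")
        for line in fh:
            read_id, ko_id, protein_id, length = line.rstrip("\n").split("\t")
            out.append(
                ReadAssignment(
                    read_id=read_id,
                    ko_id=ko_id,
                    effective_protein_length_aa=int(length),
                    winning_protein_id=protein_id,
                )
            )
    return out
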