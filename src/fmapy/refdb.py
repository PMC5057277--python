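"""Reference annotation model: protein -> KO with lengths, KO -> pathway,
operon -> KO members.

The reference emulates a KEGG-filtered protein database: every retained
protein carries a KO assignment and an amino-acid length, and comes from one
of the cellular domains relevant to microbiome profiling (bacteria, archaea,
fungi). Pathway and operon tables are flattened (feature_id, ko_id) pair
lists, in the style of the ODB3 operon database.

All tables are tab-separated UTF-8 text; lines starting with '#' are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_DOMAINS = frozenset({"bacteria", "archaea", "fungi"})

_PROTEIN_COLUMNS = ["protein_id", "ko_id", "length_aa", "taxon_domain"]


class ReferenceError(ValueError):
    """Malformed or empty reference input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One reference protein with its KO assignment.

    length_aa is in amino acids; the x3 nucleotide conversion happens only
    inside the RPKM formula.
    """

    protein_id: str
    ko_id: str
    length_aa: int
    taxon_domain: str = "bacteria"

    def __post_init__(self) -> None:
        if self.length_aa < 1:
            raise ReferenceError(
                f"protein {self.protein_id!r}: length_aa must be >= 1, "
                f"got {self.length_aa}"
            )


@dataclass(frozen=True)
class PathwaySet:
    """A KEGG pathway as a set of member KOs."""

    pathway_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ReferenceError(f"pathway {self.pathway_id!r} has no members")


@dataclass(frozen=True)
class OperonSet:
    """An operon: an ordered list of member KOs plus a free-text label.

    Source tables may repeat a KO within an operon; ``member_set`` is the
    deduplicated view used by the all-members differential-abundance rule.
    """

    operon_id: str
    members: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ReferenceError(f"operon {self.operon_id!r} has no members")

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


@dataclass
class ReferenceDB:
    """Validated reference the whole pipeline queries."""

    proteins: dict[str, ProteinRecord]
    pathways: list[PathwaySet] = field(default_factory=list)
    operons: list[OperonSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ko_universe: frozenset[str] = frozenset(
            p.ko_id for p in self.proteins.values()
        )
        self._pathway_index = {p.pathway_id: p for p in self.pathways}
        self._operon_index = {o.operon_id: o for o in self.operons}
        dangling = sorted(
            ko
            for feat in [*self.pathways, *self.operons]
            for ko in (
                feat.members
                if isinstance(feat, PathwaySet)
                else feat.member_set
            )
            if ko not in self.ko_universe
        )
        if dangling:
            logger.warning(
                "%d KO(s) referenced by pathways/operons are absent from the "
                "protein table (kept): %s",
                len(dangling),
                ", ".join(dangling[:10]),
            )

    def protein(self, protein_id: str) -> ProteinRecord:
        return self.proteins[protein_id]

    def pathway(self, pathway_id: str) -> PathwaySet:
        try:
            return self._pathway_index[pathway_id]
        except KeyError:
            raise KeyError(f"unknown pathway id {pathway_id!r}") from None

    def operon(self, operon_id: str) -> OperonSet:
        try:
            return self._operon_index[operon_id]
        except KeyError:
            raise KeyError(f"unknown operon id {operon_id!r}") from None


def pathway_size(db: ReferenceDB, pathway_id: str) -> int:
    """Number of unique member KOs of a pathway (enrichment denominator)."""
    return len(db.pathway(pathway_id).members)


def _read_tsv(path: Path | str, names: Sequence[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", dtype=str,
            header=0 if names is None else None, names=names,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(names) if names else [])
    return df


def _load_protein_table(path: Path | str) -> dict[str, ProteinRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _PROTEIN_COLUMNS if c not in df.columns]
    if missing:
        raise ReferenceError(
            f"{path}: protein table missing column(s) {missing}; "
            f"expected header {_PROTEIN_COLUMNS}"
        )
    proteins: dict[str, ProteinRecord] = {}
    n_dropped = 0
    n_expanded = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        ko_field = (row.ko_id or "").strip() if isinstance(row.ko_id, str) else ""
        if not ko_field:
            n_dropped += 1
            continue
        try:
            length = int(row.length_aa)
        except (TypeError, ValueError):
            raise ReferenceError(
                f"{path}, line {i}: unparseable length_aa {row.length_aa!r}"
            ) from None
        # a protein annotated to several KOs is expanded to one record per KO
        kos = [k.strip() for k in ko_field.split(",") if k.strip()]
        if len(kos) > 1:
            n_expanded += 1
        for j, ko in enumerate(kos):
            pid = row.protein_id if j == 0 else f"{row.protein_id}|{ko}"
            try:
                proteins[pid] = ProteinRecord(
                    protein_id=pid,
                    ko_id=ko,
                    length_aa=length,
                    taxon_domain=(row.taxon_domain or "other"),
                )
            except ReferenceError as exc:
                raise ReferenceError(f"{path}, line {i}: {exc}") from None
    if n_dropped:
        logger.info("%s: dropped %d protein row(s) without a KO", path, n_dropped)
    if n_expanded:
        logger.info(
            "%s: expanded %d multi-KO protein row(s) into one record per KO",
            path, n_expanded,
        )
    if not proteins:
        raise ReferenceError(f"{path}: empty protein table")
    return proteins


def _load_pathway_table(path: Path | str) -> list[PathwaySet]:
    df = _read_tsv(path, names=["pathway_id", "pathway_name", "ko_id"])
    if df.empty:
        return []
    pathways = []
    for pid, grp in df.groupby("pathway_id", sort=True):
        name = next((n for n in grp["pathway_name"] if isinstance(n, str)), "")
        members = frozenset(k for k in grp["ko_id"] if isinstance(k, str) and k)
        if not members:
            raise ReferenceError(f"{path}: pathway {pid!r} has no member KOs")
        pathways.append(PathwaySet(pathway_id=str(pid), name=name, members=members))
    return pathways


def _load_operon_table(path: Path | str) -> list[OperonSet]:
    df = _read_tsv(path, names=["operon_id", "ko_id", "label"])
    if df.empty:
        return []
    operons = []
    for oid, grp in df.groupby("operon_id", sort=True):
        members = tuple(k for k in grp["ko_id"] if isinstance(k, str) and k)
        label = next((l for l in grp["label"] if isinstance(l, str)), "")
        if not members:
            raise ReferenceError(f"{path}: operon {oid!r} has no member KOs")
        operons.append(OperonSet(operon_id=str(oid), members=members, label=label))
    return operons


def load_reference(
    protein_table_path: Path | str,
    pathway_table_path: Path | str | None = None,
    operon_table_path: Path | str | None = None,
) -> ReferenceDB:
    """Load a reference from the three TSV tables.

    Protein rows with an empty KO are dropped (counted in the log); KOs
    referenced by pathway/operon tables but absent from the protein table are
    kept with a warning — enrichment universes are configurable downstream.
    """
    proteins = _load_protein_table(protein_table_path)
    pathways = _load_pathway_table(pathway_table_path) if pathway_table_path else []
    operons = _load_operon_table(operon_table_path) if operon_table_path else []
    return ReferenceDB(proteins=proteins, pathways=pathways, operons=operons)


def build_reference(
    raw_annotations: pd.DataFrame | Iterable[Mapping[str, object]],
    allowed_domains: Iterable[str] = DEFAULT_DOMAINS,
    pathways: list[PathwaySet] | None = None,
    operons: list[OperonSet] | None = None,
) -> ReferenceDB:
    """Build a reference from raw annotation rows, KFU-style.

    Retains only rows with a non-empty KO assignment whose taxon domain is in
    ``allowed_domains`` (default: bacteria, archaea, fungi) — the same filter
    used to construct a KEGG-restricted protein reference from a general
    protein annotation dump.
    """
    allowed = frozenset(allowed_domains)
    if not allowed:
        raise ReferenceError("allowed_domains must be non-empty")
    df = (
        raw_annotations
        if isinstance(raw_annotations, pd.DataFrame)
        else pd.DataFrame(list(raw_annotations))
    )
    missing = [c for c in _PROTEIN_COLUMNS if c not in df.columns]
    if missing:
        raise ReferenceError(f"raw annotations missing column(s) {missing}")
    proteins: dict[str, ProteinRecord] = {}
    for row in df.itertuples(index=False):
        ko = (row.ko_id or "").strip() if isinstance(row.ko_id, str) else ""
        if not ko or row.taxon_domain not in allowed:
            continue
        proteins[str(row.protein_id)] = ProteinRecord(
            protein_id=str(row.protein_id),
            ko_id=ko,
            length_aa=int(row.length_aa),
            taxon_domain=str(row.taxon_domain),
        )
    if not proteins:
        raise ReferenceError("empty reference: no rows passed the KO/domain filter")
    logger.info(
        "build_reference: retained %d/%d protein rows", len(proteins), len(df)
    )
    return ReferenceDB(
        proteins=proteins, pathways=pathways or [], operons=operons or []
    )


def write_reference(db: ReferenceDB, out_dir: Path | str) -> dict[str, Path]:
    """Write the three reference tables back to TSV (round-trippable)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": out_dir / "proteins.tsv",
        "pathways": out_dir / "pathways.tsv",
        "operons": out_dir / "operons.tsv",
    }
    with open(paths["proteins"], "w") as fh:
        fh.write("protein_id\tko_id\tlength_aa\ttaxon_domain\n")
        for pid in sorted(db.proteins):
            p = db.proteins[pid]
            fh.write(f"{p.protein_id}\t{p.ko_id}\t{p.length_aa}\t{p.taxon_domain}\n")
    with open(paths["pathways"], "w") as fh:
        for pw in db.pathways:
            for ko in sorted(pw.members):
                fh.write(f"{pw.pathway_id}\t{pw.name}\t{ko}\n")
    with open(paths["operons"], "w") as fh:
        for op in db.operons:
            for ko in op.members:
                fh.write(f"{op.operon_id}\t{ko}\t{op.label}\n")
    return paths
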