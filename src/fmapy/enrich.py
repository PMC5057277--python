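"""Operon- and pathway-level enrichment over the DA KO set.

An operon is called differentially abundant only when *all* of its member
KOs are DA (the all-members rule); those candidate operons are then
annotated with a two-sided Fisher's exact p-value against the chosen KO
universe. Pathways are tested whenever they contain at least one DA KO.
The 2x2 table is

    [ in-feature & DA     in-feature & not-DA  ]
    [ out-feature & DA    out-feature & not-DA ]

and the two-sided p sums the probabilities of all fixed-margin tables whose
point probability does not exceed the observed one. Coverage is the
fraction of a feature's (universe-restricted) members that are DA, and
avg_log2_fc averages the log2 fold changes of the feature's DA members.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Set

from scipy import stats

from fmapy.compare import ComparisonResult, bh_fdr
from fmapy.refdb import OperonSet, ReferenceDB


@dataclass
class EnrichmentResult:
    """Enrichment of one feature (operon or pathway) in the DA KO set."""

    feature_id: str
    feature_kind: str  # operon | pathway
    name: str
    ko_count: int  # DA KOs in the feature
    feature_size: int  # feature members within the universe
    coverage: float  # ko_count / feature_size
    avg_log2_fc: float
    p_value: float
    q_value: float
    da_ko_list: tuple[str, ...]
    single_member: bool = False  # size-1 features are weak evidence


def da_operons(da_kos: Set[str], db: ReferenceDB) -> list[OperonSet]:
    """Operons whose full (deduplicated) member set is contained in da_kos."""
    da = frozenset(da_kos)
    return [op for op in db.operons if op.member_set and op.member_set <= da]


def fisher_enrichment(
    da_kos: Set[str], feature: Set[str], universe: Set[str]
) -> tuple[float, int, float]:
    """Two-sided Fisher's exact test of DA enrichment in a feature.

    Both the feature and the DA set are intersected with the universe first.
    Returns (p_value, ko_count, coverage) with ko_count = |feature ∩ DA| and
    coverage = ko_count / |feature ∩ universe|.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    feat = frozenset(feature) & universe
    if not feat:
        raise ValueError("feature has no members within the universe")
    da = frozenset(da_kos) & universe
    a = len(feat & da)
    b = len(feat) - a
    c = len(da) - a
    d = len(universe) - len(feat) - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p), a, a / len(feat)


def enrich_features(
    comparison: ComparisonResult,
    db: ReferenceDB,
    kind: str,
    universe_mode: str = "reference",
    detected_kos: Set[str] | None = None,
) -> list[EnrichmentResult]:
    """Enrichment results for all qualifying features of one kind.

    Pathway candidates are every pathway containing >= 1 DA KO; operon
    candidates are the all-members-DA operons. The universe defaults to the
    full reference KO set; ``universe_mode='detected'`` restricts it to KOs
    observed in the data (``detected_kos``, falling back to the tested KO
    set). BH q-values are computed over the tested features of this kind,
    and results are sorted by ascending p.
    """
    if kind not in {"operon", "pathway"}:
        raise ValueError(f"unknown feature kind {kind!r}")
    if universe_mode not in {"reference", "detected"}:
        raise ValueError(f"unknown universe mode {universe_mode!r}")
    da = comparison.da_kos
    if universe_mode == "reference":
        universe = frozenset(db.ko_universe)
    else:
        universe = frozenset(
            detected_kos if detected_kos is not None else comparison.table.index
        )

    if kind == "pathway":
        candidates = [
            (pw.pathway_id, pw.name, frozenset(pw.members))
            for pw in db.pathways
            if pw.members & da
        ]
    else:
        candidates = [
            (op.operon_id, op.label, op.member_set) for op in da_operons(da, db)
        ]

    results: list[EnrichmentResult] = []
    for fid, name, members in candidates:
        members_in_universe = members & universe
        if not members_in_universe:
            continue
        p, ko_count, coverage = fisher_enrichment(da, members, universe)
        da_members = sorted(members_in_universe & da)
        lfcs = [comparison.log2fc_of(k) for k in da_members if k in comparison.table.index]
        avg_lfc = sum(lfcs) / len(lfcs) if lfcs else float("nan")
        results.append(
            EnrichmentResult(
                feature_id=fid,
                feature_kind=kind,
                name=name,
                ko_count=ko_count,
                feature_size=len(members_in_universe),
                coverage=coverage,
                avg_log2_fc=avg_lfc,
                p_value=p,
                q_value=1.0,
                da_ko_list=tuple(da_members),
                single_member=len(members_in_universe) == 1,
            )
        )
    if results:
        qs = bh_fdr([r.p_value for r in results])
        for r, q in zip(results, qs):
            r.q_value = q
    results.sort(key=lambda r: (r.p_value, r.feature_id))
    return results


def write_enrichment(results: Iterable[EnrichmentResult], out_path: Path | str) -> None:
    with open(out_path, "w") as fh:
        fh.write(
            "feature_id\tkind\tname\tko_count\tfeature_size\tcoverage\t"
            "avg_log2_fc\tp_value\tq_value\tda_ko_list\n"
        )
        for r in results:
            fh.write(
                f"{r.feature_id}\t{r.feature_kind}\t{r.name}\t{r.ko_count}\t"
                f"{r.feature_size}\t{r.coverage:.3f}\t{r.avg_log2_fc:.4f}\t"
                f"{r.p_value:.6g}\t{r.q_value:.6g}\t{','.join(r.da_ko_list)}\n"
            )
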