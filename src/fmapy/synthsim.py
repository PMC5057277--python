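"""Seed-reproducible synthetic data: reference tables and alignment files
with known ground truth.

The generator emulates what the pipeline consumes in a real study — a
KO-annotated protein reference with pathway and operon structure, and
per-sample best-hit alignment files — while recording the truth needed to
score every downstream stage: per-KO relative abundances per group, spiked
fold changes, and the realized read counts per sample.

Abundance model: each KO receives a lognormal base abundance; group
relative abundances are the normalized base abundances, with spiked KOs
multiplied by 2^true_log2_fc in the case group before normalization (spike
directions alternate +/- so the case library is not dominated by one-sided
compositional shift). Realized per-sample counts are negative-binomial
around expectation reads_per_sample x relative abundance, so
over-dispersion stresses both test methods. Each read emits one primary
hit to a random protein of its source KO, with identity and e-value drawn
from configured noise ranges; optional decoy secondary hits always carry a
strictly lower bitscore, so best-hit truth stays unambiguous.

One RNG stream is derived per sample from (seed, sample_id), so adding a
sample never perturbs existing ones, and a fixed seed yields byte-identical
output files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from fmapy.refdb import ReferenceDB, load_reference

_REF_STREAM = 7_777_777  # fixed sub-stream key for reference generation


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with study-scale defaults.

    dispersion is the negative-binomial size parameter (smaller = more
    over-dispersed); identity is percent identity of simulated hits;
    evalue bounds are log-uniform.
    """

    n_kos: int = 500
    proteins_per_ko: tuple[int, int] = (1, 3)
    protein_length_range_aa: tuple[int, int] = (100, 600)
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (5, 15)
    n_operons: int = 30
    operon_size_range: tuple[int, int] = (2, 5)
    groups: dict[str, int] = field(
        default_factory=lambda: {"control": 10, "case": 10}
    )
    reads_per_sample: int = 20_000
    spiked_kos: int = 50
    true_log2_fc: float = 3.0
    dispersion: float = 5.0
    identity_range: tuple[float, float] = (85.0, 99.0)
    evalue_range: tuple[float, float] = (1e-30, 1e-5)
    decoy_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_kos < 1 or self.reads_per_sample < 1:
            raise ValueError("n_kos and reads_per_sample must be positive")
        if self.spiked_kos > self.n_kos:
            raise ValueError("spiked_kos cannot exceed n_kos")
        if self.operon_size_range[1] > self.n_kos:
            raise ValueError("operon size exceeds the number of KOs")
        if self.pathway_size_range[1] > self.n_kos:
            raise ValueError("pathway size exceeds the number of KOs")
        if len(self.groups) < 2 and self.spiked_kos:
            raise ValueError("spiked fold changes require at least 2 groups")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in (
            "proteins_per_ko",
            "protein_length_range_aa",
            "pathway_size_range",
            "operon_size_range",
            "identity_range",
            "evalue_range",
        ):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class GroundTruth:
    """What the simulator knows and the pipeline must recover."""

    per_ko: pd.DataFrame  # index ko_id: spiked, true_log2_fc, abund_<group>...
    realized_counts: pd.DataFrame  # KO x sample realized read counts
    design: dict[str, str]  # sample -> group

    @property
    def spiked(self) -> frozenset[str]:
        return frozenset(self.per_ko.index[self.per_ko["spiked"]])

    def write(self, out_dir: Path | str) -> None:
        out_dir = Path(out_dir)
        per_ko = self.per_ko.copy()
        per_ko.index.name = "ko_id"
        per_ko.to_csv(out_dir / "truth.tsv", sep="\t")
        counts = self.realized_counts.copy()
        counts.index.name = "ko_id"
        counts.to_csv(out_dir / "realized_counts.tsv", sep="\t")
        with open(out_dir / "design.tsv", "w") as fh:
            fh.write("sample_id\tgroup\n")
            for sample, group in self.design.items():
                fh.write(f"{sample}\t{group}\n")


def _rng_for(seed: int, stream_key: int | str) -> np.random.Generator:
    if isinstance(stream_key, str):
        stream_key = zlib.crc32(stream_key.encode())
    return np.random.default_rng([seed, stream_key])


def _ko_ids(n: int) -> list[str]:
    return [f"K{i:05d}" for i in range(1, n + 1)]


def simulate_reference(cfg: SimulationConfig, out_dir: Path | str) -> ReferenceDB:
    """Write protein/pathway/operon TSVs and return the loaded ReferenceDB.

    Operon members are drawn from within one pathway's membership whenever a
    pathway is large enough — mirroring how real operons nest inside
    pathways — otherwise from the full KO set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng_for(cfg.seed, _REF_STREAM)
    kos = _ko_ids(cfg.n_kos)

    lo_p, hi_p = cfg.proteins_per_ko
    lo_l, hi_l = cfg.protein_length_range_aa
    with open(out_dir / "proteins.tsv", "w") as fh:
        fh.write("protein_id\tko_id\tlength_aa\ttaxon_domain\n")
        for ko in kos:
            n_prot = int(rng.integers(lo_p, hi_p + 1))
            lengths = rng.integers(lo_l, hi_l + 1, size=n_prot)
            for j, length in enumerate(lengths, start=1):
                fh.write(f"{ko}_p{j}\t{ko}\t{int(length)}\tbacteria\n")

    lo, hi = cfg.pathway_size_range
    pathway_members: dict[str, list[str]] = {}
    with open(out_dir / "pathways.tsv", "w") as fh:
        for i in range(1, cfg.n_pathways + 1):
            pid = f"map{i:05d}"
            size = int(rng.integers(lo, hi + 1))
            members = sorted(rng.choice(kos, size=size, replace=False))
            pathway_members[pid] = members
            for ko in members:
                fh.write(f"{pid}\tsynthetic pathway {i}\t{ko}\n")

    lo, hi = cfg.operon_size_range
    pathway_ids = sorted(pathway_members)
    with open(out_dir / "operons.tsv", "w") as fh:
        for i in range(1, cfg.n_operons + 1):
            oid = f"OP{i:05d}"
            size = int(rng.integers(lo, hi + 1))
            pool: Sequence[str] = kos
            if pathway_ids:
                pid = pathway_ids[int(rng.integers(0, len(pathway_ids)))]
                if len(pathway_members[pid]) >= size:
                    pool = pathway_members[pid]
            members = sorted(rng.choice(pool, size=size, replace=False))
            for ko in members:
                fh.write(f"{oid}\t{ko}\tsynthetic operon {i}\n")

    return load_reference(
        out_dir / "proteins.tsv", out_dir / "pathways.tsv", out_dir / "operons.tsv"
    )


def _group_abundances(
    cfg: SimulationConfig, rng: np.random.Generator, kos: list[str]
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Per-group relative abundances plus spike bookkeeping.

    Returns (per-KO truth frame, relative-abundance matrix group x KO,
    spike flags). The first group is the reference; all other groups carry
    the spikes.
    """
    base = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_kos)
    spiked_idx = rng.choice(cfg.n_kos, size=cfg.spiked_kos, replace=False)
    signs = np.where(np.arange(cfg.spiked_kos) % 2 == 0, 1.0, -1.0)
    lfc = np.zeros(cfg.n_kos)
    lfc[spiked_idx] = signs * cfg.true_log2_fc
    spiked = np.zeros(cfg.n_kos, dtype=bool)
    spiked[spiked_idx] = True

    group_names = list(cfg.groups)
    rel = np.zeros((len(group_names), cfg.n_kos))
    rel[0] = base / base.sum()
    for gi in range(1, len(group_names)):
        weighted = base * np.exp2(lfc)
        rel[gi] = weighted / weighted.sum()

    per_ko = pd.DataFrame(
        {
            "spiked": spiked,
            "true_log2_fc": lfc,
            **{f"abund_{g}": rel[gi] for gi, g in enumerate(group_names)},
        },
        index=kos,
    )
    return per_ko, rel, spiked


def simulate_alignments(
    cfg: SimulationConfig, db: ReferenceDB, out_dir: Path | str
) -> GroundTruth:
    """Write per-sample outfmt-6 alignment files plus the ground truth.

    Every generated file parses through the alignment_filter stage. With
    noise-free settings (identity range above the filter cutoff, small
    e-values, no decoys) the filtered raw counts equal the realized truth
    counts exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    kos = _ko_ids(cfg.n_kos)
    proteins_by_ko: dict[str, list] = {}
    for p in db.proteins.values():
        proteins_by_ko.setdefault(p.ko_id, []).append(p)
    for ko in proteins_by_ko:
        proteins_by_ko[ko].sort(key=lambda p: p.protein_id)
    missing = [ko for ko in kos if ko not in proteins_by_ko]
    if missing:
        raise ValueError(f"reference lacks proteins for KO(s): {missing[:5]}")
    all_proteins = sorted(db.proteins.values(), key=lambda p: p.protein_id)

    truth_rng = _rng_for(cfg.seed, "ground-truth")
    per_ko, rel, _ = _group_abundances(cfg, truth_rng, kos)

    group_names = list(cfg.groups)
    design: dict[str, str] = {}
    for g, n in cfg.groups.items():
        for i in range(1, n + 1):
            design[f"{g}{i:02d}"] = g

    lo_e, hi_e = np.log10(cfg.evalue_range[0]), np.log10(cfg.evalue_range[1])
    counts = pd.DataFrame(0, index=kos, columns=list(design), dtype=np.int64)
    for sample, group in design.items():
        rng = _rng_for(cfg.seed, sample)
        gi = group_names.index(group)
        mu = cfg.reads_per_sample * rel[gi]
        size = cfg.dispersion
        # NB(size, p) with mean mu: p = size / (size + mu)
        n_reads = np.where(
            mu > 0, rng.negative_binomial(size, size / (size + mu)), 0
        )
        counts[sample] = n_reads
        lines: list[str] = []
        read_no = 0
        for ko, n_ko in zip(kos, n_reads):
            prots = proteins_by_ko[ko]
            for _ in range(int(n_ko)):
                read_no += 1
                rid = f"{sample}_r{read_no:07d}"
                prot = prots[int(rng.integers(0, len(prots)))]
                ident = rng.uniform(*cfg.identity_range)
                ev = 10.0 ** rng.uniform(lo_e, hi_e)
                alen = int(rng.integers(25, 46))
                mism = int(round(alen * (1 - ident / 100.0)))
                sstart = int(rng.integers(1, max(2, prot.length_aa - alen)))
                bits = round(2.0 * alen * ident / 100.0, 1)
                lines.append(
                    f"{rid}\t{prot.protein_id}\t{ident:.1f}\t{alen}\t{mism}\t0\t"
                    f"1\t{alen * 3}\t{sstart}\t{sstart + alen - 1}\t"
                    f"{ev:.3e}\t{bits:.1f}"
                )
                if cfg.decoy_prob > 0 and rng.random() < cfg.decoy_prob:
                    decoy = all_proteins[int(rng.integers(0, len(all_proteins)))]
                    d_ident = rng.uniform(*cfg.identity_range)
                    d_bits = round(bits - rng.uniform(5.0, 20.0), 1)
                    d_ev = 10.0 ** rng.uniform(lo_e, hi_e)
                    d_start = int(rng.integers(1, max(2, decoy.length_aa - alen)))
                    lines.append(
                        f"{rid}\t{decoy.protein_id}\t{d_ident:.1f}\t{alen}\t"
                        f"{mism}\t0\t1\t{alen * 3}\t{d_start}\t"
                        f"{d_start + alen - 1}\t{d_ev:.3e}\t{d_bits:.1f}"
                    )
        with open(out_dir / f"{sample}.m8", "w") as fh:
            fh.write("\n".join(lines))
            if lines:
                fh.write("\n")

    truth = GroundTruth(per_ko=per_ko, realized_counts=counts, design=design)
    truth.write(out_dir)
    return truth


def simulate_study(
    cfg: SimulationConfig, out_dir: Path | str
) -> tuple[ReferenceDB, GroundTruth]:
    """Reference + alignments in one call; files land under out_dir/ref and
    out_dir/samples."""
    out_dir = Path(out_dir)
    db = simulate_reference(cfg, out_dir / "ref")
    truth = simulate_alignments(cfg, db, out_dir / "samples")
    return db, truth
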