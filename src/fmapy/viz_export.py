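"""Visualization-ready exports: KEGG pathway-map colors and heatmap matrices.

The KEGG color file is the two-column paste format of the online pathway
mapping form (http://www.genome.jp/kegg/tool/map_pathway2.html): one DA KO
per line, colored red when over-abundant (log2 fold change > 0) and blue
when under-abundant (< 0). The heatmap export is an RPKM matrix TSV,
optionally log10(x+1)-transformed or row z-scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Set

import numpy as np
import pandas as pd

from fmapy.compare import ComparisonResult
from fmapy.quantify import AbundanceTable

# hex equivalents for the KEGG form's bgcolor syntax
_HEX = {"red": "#FF0000", "blue": "#0000FF"}


@dataclass(frozen=True)
class KeggColorLine:
    ko_id: str
    color: str  # red | blue


def kegg_colors(
    comparison: ComparisonResult, restrict_to: Set[str] | None = None
) -> list[KeggColorLine]:
    """One color line per DA KO, sorted by KO id.

    Over-abundant KOs (log2_fc > 0) are red, under-abundant (< 0) blue; a
    DA KO with log2_fc exactly 0 has no direction and is omitted.
    ``restrict_to`` optionally intersects the output with a feature's KO set
    (e.g. one pathway's members).
    """
    kos = comparison.da_kos
    if restrict_to is not None:
        kos = kos & frozenset(restrict_to)
    lines = []
    for ko in sorted(kos):
        lfc = comparison.log2fc_of(ko)
        if lfc > 0:
            lines.append(KeggColorLine(ko_id=ko, color="red"))
        elif lfc < 0:
            lines.append(KeggColorLine(ko_id=ko, color="blue"))
    return lines


def write_kegg_colors(
    lines: Iterable[KeggColorLine], out_path: Path | str, hex_colors: bool = False
) -> None:
    """Two-column TSV, no header — the KEGG web-form paste format."""
    with open(out_path, "w") as fh:
        for line in lines:
            color = _HEX[line.color] if hex_colors else line.color
            fh.write(f"{line.ko_id}\t{color}\n")


def heatmap_matrix(
    table: AbundanceTable,
    ko_subset: Set[str] | None = None,
    transform: str = "none",
) -> pd.DataFrame:
    """RPKM matrix restricted to a KO subset, with an optional transform.

    transform 'log10p1' applies log10(x + 1) elementwise; 'zscore_rows'
    centers and scales each row by its population standard deviation, with
    zero-variance rows emitted as all zeros.
    """
    mat = table.rpkm
    if ko_subset is not None:
        missing = sorted(frozenset(ko_subset) - set(table.kos))
        if missing:
            raise KeyError(f"KO(s) not in table: {missing[:10]}")
        mat = mat.loc[sorted(ko_subset)]
    mat = mat.astype(float).copy()
    if transform == "none":
        return mat
    if transform == "log10p1":
        return np.log10(mat + 1.0)
    if transform == "zscore_rows":
        mu = mat.mean(axis=1)
        sigma = mat.std(axis=1, ddof=0)
        z = mat.sub(mu, axis=0).div(sigma.replace(0.0, np.nan), axis=0)
        return z.fillna(0.0)
    raise ValueError(f"unknown transform {transform!r}")


def write_heatmap(matrix: pd.DataFrame, out_path: Path | str) -> None:
    out = matrix.copy()
    out.index.name = "ko_id"
    out.to_csv(out_path, sep="\t")
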