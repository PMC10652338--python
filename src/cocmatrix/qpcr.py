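"""Customised RT2-array relative-quantification analysis.

Ct tables (gene x sample) are normalised against the mean of five
housekeeping genes per sample, contrasted between groups per replicate
experiment with the 2^-ddCt method, averaged across replicates, and
classified as up / down / unchanged against a +-1.5 average-fold-change
threshold.  A lower limit of detection floors every Ct above 35 (and every
undetermined value) at 35 to avoid fold-change over-calculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_HKGS",
    "CT_FLOOR",
    "UP_FC",
    "CtTable",
    "FoldChangeResult",
    "apply_floor",
    "ddct_fold_change",
    "log2_transform",
    "fold_regulation",
]

DEFAULT_HKGS = ("Gusb", "Actb", "Gapdh", "B2m", "Hsp90ab1")
CT_FLOOR = 35.0
#: up-regulation call threshold on average decimal fold change; the
#: down-regulation threshold is its reciprocal
UP_FC = 1.5


@dataclass(frozen=True)
class CtTable:
    """Gene x sample Ct matrix with sample metadata.

    ``ct`` is indexed by gene with one column per sample.  ``sample_meta``
    is indexed by sample name with columns ``group`` (young/old) and
    ``replicate``.  All housekeeping genes must be present as rows.
    """

    ct: pd.DataFrame
    sample_meta: pd.DataFrame
    hkgs: tuple[str, ...] = DEFAULT_HKGS
    ct_floor: float = CT_FLOOR

    def __post_init__(self) -> None:
        missing = [h for h in self.hkgs if h not in self.ct.index]
        if missing:
            raise ValueError(f"housekeeping genes missing from Ct table: {missing}")
        extra = set(self.ct.columns) - set(self.sample_meta.index)
        if extra:
            raise ValueError(f"samples without metadata: {sorted(extra)}")
        vals = self.ct.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (np.any(finite <= 0) or np.any(finite > 45)):
            raise ValueError("Ct values must lie in (0, 45] or be missing")
        bad_groups = set(self.sample_meta["group"]) - {"young", "old"}
        if bad_groups:
            raise ValueError(f"unknown groups: {sorted(bad_groups)}")

    @property
    def target_genes(self) -> list[str]:
        return [g for g in self.ct.index if g not in self.hkgs]


@dataclass(frozen=True)
class FoldChangeResult:
    """Per-gene fold changes relative to the young group.

    ``table`` has one row per target gene with per-replicate fold changes
    (``fc_rep<k>``), the across-replicate average ``avg_fc``, ``log2_fc``
    and the regulation ``call``.
    """

    table: pd.DataFrame
    up_fc: float = UP_FC
    warnings: tuple[str, ...] = field(default_factory=tuple)

    @property
    def calls(self) -> pd.Series:
        return self.table["call"]

    @property
    def avg_fc(self) -> pd.Series:
        return self.table["avg_fc"]


def apply_floor(table: CtTable) -> CtTable:
    """Clamp every Ct above the floor — and every missing value — to the floor.

    Idempotent; values at or below the floor pass through unchanged.
    """
    ct = table.ct.astype(float).copy()
    floor = table.ct_floor
    ct = ct.where(ct <= floor, floor)
    ct = ct.fillna(floor)
    return replace(table, ct=ct)


def _call(avg_fc: float, up_fc: float) -> str:
    if avg_fc > up_fc:
        return "up"
    if avg_fc < 1.0 / up_fc:
        return "down"
    return "unchanged"


def ddct_fold_change(table: CtTable, up_fc: float = UP_FC) -> FoldChangeResult:
    """2^-ddCt fold changes of the old group relative to young.

    Per sample, dCt(gene) = Ct(gene) - mean(Ct of the housekeeping genes).
    Within each replicate experiment, ddCt(gene) = mean dCt(old) - mean
    dCt(young) and FC = 2^-ddCt; ``avg_fc`` is the arithmetic mean of the
    replicate fold changes, on which regulation calls are made.
    """
    table = apply_floor(table)
    meta = table.sample_meta
    for grp in ("young", "old"):
        if not (meta["group"] == grp).any():
            raise ValueError(f"no samples in group {grp!r}")

    hkg_mean = table.ct.loc[list(table.hkgs)].mean(axis=0)
    dct = table.ct.sub(hkg_mean, axis=1)

    replicates = sorted(meta["replicate"].unique())
    fc_cols: dict[str, pd.Series] = {}
    warnings: list[str] = []
    for rep in replicates:
        samples = meta.index[meta["replicate"] == rep]
        young = [s for s in samples if meta.loc[s, "group"] == "young"]
        old = [s for s in samples if meta.loc[s, "group"] == "old"]
        if not young or not old:
            warnings.append(f"replicate {rep}: missing a group, skipped")
            continue
        ddct = dct[old].mean(axis=1) - dct[young].mean(axis=1)
        fc_cols[f"fc_rep{rep}"] = np.power(2.0, -ddct)
    if not fc_cols:
        raise ValueError("no replicate contains both groups")

    out = pd.DataFrame(fc_cols).loc[table.target_genes]
    out["avg_fc"] = out.mean(axis=1)
    out["log2_fc"] = np.log2(out["avg_fc"])
    out["call"] = [_call(v, up_fc) for v in out["avg_fc"]]
    out.index.name = "gene"
    return FoldChangeResult(table=out, up_fc=up_fc, warnings=tuple(warnings))


def log2_transform(result: FoldChangeResult) -> pd.Series:
    """log2 of the average fold change per gene.

    On this scale the up-regulation threshold FC > 1.5 maps to
    log2(1.5) = 0.585 (3 dp) and down-regulation to -0.585.
    """
    return np.log2(result.table["avg_fc"]).rename("log2_fc")


def fold_regulation(result: FoldChangeResult) -> pd.Series:
    """Signed display convention: FC for FC >= 1, -1/FC for FC < 1."""
    fc = result.table["avg_fc"]
    return fc.where(fc >= 1.0, -1.0 / fc).rename("fold_regulation")
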