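"""Core in-memory containers.

All matrices are pandas DataFrames with feature ids on the index and
sample/specimen ids on the columns; metadata travel alongside as Series
aligned to the relevant axis.  Missing measurements are NaN, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError

GROUP_TUMOR = "tumor"
GROUP_BENIGN = "benign"


@dataclass
class MetaboliteMatrix:
    """Raw targeted-metabolomics peak areas (metabolites x samples).

    Parameters
    ----------
    values
        Non-negative raw peak areas; NaN marks missing measurements.
    method
        Per-metabolite chromatography-method label (one of the acquisition
        methods, each calibrated by its own spiked internal standards).
    is_internal_standard
        True for spiked internal-standard rows (e.g. zeatin,
        tryptophan-15N2 analogues); these calibrate the per-sample,
        per-method scale and are removed during normalization.
    """

    values: pd.DataFrame
    method: pd.Series
    is_internal_standard: pd.Series

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate metabolite id(s): {dup}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample id(s): {dup}")
        self.values.index.name = "feature_id"
        self.method = self.method.reindex(idx)
        self.is_internal_standard = self.is_internal_standard.reindex(idx).astype(bool)
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise FormatError("negative raw abundance encountered")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SampleAnnotation:
    """Per-sample group labels (tumor / benign) and cohort membership."""

    table: pd.DataFrame  # index: sample_id; columns: group, cohort

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample id(s) in annotation: {dup}")
        bad = set(self.table["group"]) - {GROUP_TUMOR, GROUP_BENIGN}
        if bad:
            raise FormatError(f"unknown group label(s): {sorted(bad)}")

    def ids_in_group(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])


@dataclass
class ExpressionCohort:
    """A gene-expression cohort: log2 expression plus clinical outcomes.

    ``clinical`` is indexed by specimen id with columns ``time`` (study time
    units), ``event`` (1 = death observed, 0 = censored), ``group``
    (tumor/benign) and ``cohort``.  Survival fields may be NaN for benign
    specimens, which never enter survival analysis.
    """

    cohort_id: str
    expression: pd.DataFrame  # genes x specimens, log2 units
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        if self.expression.index.has_duplicates:
            dup = self.expression.index[self.expression.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene id(s): {dup}")

    def tumor_specimens(self) -> list[str]:
        return list(self.clinical.index[self.clinical["group"] == GROUP_TUMOR])

    def survival_records(self) -> pd.DataFrame:
        """Clinical rows with usable (time, event), restricted to tumors."""
        surv = self.clinical[self.clinical["group"] == GROUP_TUMOR]
        return surv.dropna(subset=["time", "event"])


@dataclass
class IntegratedSignature:
    """Gene signature with log2 fold-changes and induced/repressed direction.

    ``direction`` is derived from the sign of the fold-change: induced iff
    log2_fc > 0.
    """

    entries: pd.DataFrame  # index: gene_symbol; columns: log2_fc, direction

    DIRECTION_INDUCED = "induced"
    DIRECTION_REPRESSED = "repressed"

    @classmethod
    def from_fold_changes(cls, fold_changes: pd.Series) -> "IntegratedSignature":
        fc = fold_changes.astype(float)
        if fc.index.has_duplicates:
            dup = fc.index[fc.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene symbol(s) in signature: {dup}")
        direction = np.where(fc.to_numpy() > 0, cls.DIRECTION_INDUCED, cls.DIRECTION_REPRESSED)
        entries = pd.DataFrame({"log2_fc": fc, "direction": direction})
        entries.index.name = "gene_symbol"
        return cls(entries)

    @property
    def genes(self) -> list[str]:
        return list(self.entries.index)

    @property
    def induced(self) -> list[str]:
        e = self.entries
        return list(e.index[e["direction"] == self.DIRECTION_INDUCED])

    @property
    def repressed(self) -> list[str]:
        e = self.entries
        return list(e.index[e["direction"] == self.DIRECTION_REPRESSED])

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, genes) -> "IntegratedSignature":
        return IntegratedSignature(self.entries.loc[list(genes)].copy())


@dataclass
class GeneSetCollection:
    """Named gene sets plus a gene universe (explicit or derived)."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}
        if self.universe is not None:
            self.universe = frozenset(self.universe)

    def derived_universe(self) -> frozenset[str]:
        if self.universe is not None:
            return self.universe
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)


@dataclass
class MetaboliteGeneMap:
    """metabolite_id -> set of (upper-cased) gene symbols.

    Lookups of unmapped metabolites return the empty set rather than raising.
    """

    entries: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = {
            m: frozenset(g.upper() for g in genes) for m, genes in self.entries.items()
        }

    def genes_for(self, metabolite_id: str) -> frozenset[str]:
        return self.entries.get(metabolite_id, frozenset())


@dataclass
class GroundTruth:
    """Planted structure of a synthetic data set, for recovery tests."""

    true_diff_metabolites: frozenset[str] = frozenset()
    true_diff_genes: dict[str, int] = field(default_factory=dict)  # gene -> +1/-1
    planted_signature: list[tuple[str, int]] = field(default_factory=list)
    latent_score: pd.Series | None = None  # per-specimen standardized score
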