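"""Model/Results interface over the WWE caller.

``DMRModel`` binds aligned two-group methylation counts to a set of
calling criteria; ``fit()`` runs the weighted Welch expansion and returns
a ``DMRResults`` carrying the called regions, their region-level p- and
BH-adjusted q-values, summary tables, writers, gene annotation and
benchmarking against a truth interval set.

>>> model = DMRModel.from_files(["a1.txt", "a2.txt"], ["b1.txt", "b2.txt"])
>>> res = model.fit()
>>> print(res.summary())
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .annotate import AnnotatedDMR, annotate_dmrs, annotation_strings
from .benchmark import BenchmarkReport, IntervalSet, evaluate
from .caller import DMRCriteria, call_dmrs, parameter_sweep, site_verdicts
from .containers import DMR, GeneInterval, GroupedCounts, SiteTable, dmrs_to_frame


class DMRModel:
    """Two-group differential methylation model on aligned count matrices.

    Parameters
    ----------
    data : GroupedCounts
        Position-aligned per-replicate methylated/coverage counts.
    criteria : DMRCriteria, optional
        Calling thresholds; defaults to the standard seven defaults.
    """

    def __init__(self, data: GroupedCounts,
                 criteria: DMRCriteria | None = None):
        self.data = data
        self.criteria = criteria if criteria is not None else DMRCriteria()

    @classmethod
    def from_samples(cls, group_a: Sequence[SiteTable],
                     group_b: Sequence[SiteTable],
                     criteria: DMRCriteria | None = None,
                     merge_strands: bool = False) -> "DMRModel":
        """Build from in-memory sample tables (intersection alignment)."""
        if merge_strands:
            group_a = [mio.merge_cpg_strands(t) for t in group_a]
            group_b = [mio.merge_cpg_strands(t) for t in group_b]
        return cls(mio.align_groups(group_a, group_b), criteria=criteria)

    @classmethod
    def from_files(cls, group_a: Sequence, group_b: Sequence,
                   dialect="auto", criteria: DMRCriteria | None = None,
                   merge_strands: bool = False) -> "DMRModel":
        """Read each group's sample files (auto-detected dialect) and align."""
        tables_a = [mio.read_sample(p, dialect=dialect) for p in group_a]
        tables_b = [mio.read_sample(p, dialect=dialect) for p in group_b]
        return cls.from_samples(tables_a, tables_b, criteria=criteria,
                                merge_strands=merge_strands)

    def fit(self) -> "DMRResults":
        """Run the weighted Welch expansion and return the results."""
        verdicts = site_verdicts(self.data, self.criteria)
        dmrs = call_dmrs(self.data, self.criteria, verdicts=verdicts)
        return DMRResults(model=self, dmrs=dmrs, verdicts=verdicts)

    def sweep(self, grid: Mapping[str, Sequence]) -> pd.DataFrame:
        """DMR counts over a Cartesian grid of criterion values."""
        return parameter_sweep(self.data, grid, criteria=self.criteria)


class DMRResults:
    """Called DMRs plus diagnostics from one :meth:`DMRModel.fit` run."""

    def __init__(self, model: DMRModel, dmrs: list[DMR],
                 verdicts: pd.DataFrame):
        self.model = model
        self.dmrs = dmrs
        self.verdicts = verdicts
        self.annotated: list[AnnotatedDMR] | None = None

    def __len__(self) -> int:
        return len(self.dmrs)

    @property
    def criteria(self) -> DMRCriteria:
        return self.model.criteria

    def to_dataframe(self) -> pd.DataFrame:
        df = dmrs_to_frame(self.dmrs)
        if self.annotated is not None:
            df["genes"] = annotation_strings(self.annotated)
        return df

    def to_tsv(self, path) -> None:
        mio.write_dmrs(self.dmrs, path, format="tsv")

    def to_bed(self, path) -> None:
        mio.write_dmrs(self.dmrs, path, format="bed")

    def intervals(self) -> IntervalSet:
        return IntervalSet.from_dmrs(self.dmrs)

    def annotate(self, genes: Sequence[GeneInterval],
                 max_distance: int = 15_000) -> list[AnnotatedDMR]:
        """Attach gene-proximity annotation (kept on the results object)."""
        self.annotated = annotate_dmrs(self.dmrs, genes,
                                       max_distance=max_distance)
        return self.annotated

    def benchmark(self, truth: IntervalSet) -> BenchmarkReport:
        """Evaluate the called regions against planted truth intervals."""
        return evaluate(self.intervals(), truth)

    def summary(self) -> str:
        """Plain-text summary of the run and the called regions."""
        c = self.criteria
        n_hyper = sum(1 for d in self.dmrs if d.direction == "hyper")
        n_hypo = len(self.dmrs) - n_hyper
        n_qual = int(self.verdicts["qualifies"].sum())
        lines = [
            "Weighted Welch Expansion DMR results",
            "=" * 54,
            f"Sites tested:          {self.model.data.n_sites}",
            f"Qualifying sites:      {n_qual}",
            f"Replicates (A vs B):   {self.model.data.r_a} vs {self.model.data.r_b}",
            f"DMRs called:           {len(self.dmrs)} "
            f"({n_hyper} hyper, {n_hypo} hypo in B vs A)",
            "Criteria: "
            f"min_coverage={c.min_coverage}, min_diff={c.min_diff}%, "
            f"max_p={c.max_p}, min_cpn={c.min_cpn},",
            f"          min_span={c.min_span}, max_gap={c.max_gap}, "
            f"max_similar={c.max_similar}",
            "-" * 54,
        ]
        if self.dmrs:
            df = self.to_dataframe()
            with pd.option_context("display.max_rows", 20,
                                   "display.width", 120):
                lines.append(df.to_string(index=False,
                                          float_format=lambda x: f"{x:.4g}"))
        else:
            lines.append("(no DMRs)")
        return "\n".join(lines)
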