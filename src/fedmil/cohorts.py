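"""Published multi-site cohort accounting for the two WSI benchmarks.

Per-site slide counts of the PANDA prostate-biopsy cohort (5 simulated
centres, positive vs negative slides) and the TCGA-NSCLC lung cohort
(3 centres, LUAD vs LUSC), as published, together with the published
row/column totals.  Used to configure realistic site sizes and to check
that the accounting is internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CohortTable", "PANDA", "TCGA_NSCLC"]


@dataclass(frozen=True)
class CohortTable:
    """Per-site counts for a two-class multi-centre cohort."""

    name: str
    class_names: tuple[str, str]
    per_site: dict[str, tuple[int, ...]]  # class name -> count per site
    published_class_totals: dict[str, int]
    published_site_totals: tuple[int, ...]
    published_grand_total: int

    @property
    def n_sites(self) -> int:
        return len(self.published_site_totals)

    def class_total(self, cls: str) -> int:
        return sum(self.per_site[cls])

    def site_total(self, i: int) -> int:
        return sum(self.per_site[c][i] for c in self.class_names)

    def grand_total(self) -> int:
        return sum(self.class_total(c) for c in self.class_names)

    def site_prevalence(self, i: int) -> float:
        """Fraction of the first-listed class at site i."""
        return self.per_site[self.class_names[0]][i] / self.site_total(i)

    def consistent(self) -> bool:
        """Do all computed sums match the published totals?"""
        return (
            all(self.class_total(c) == self.published_class_totals[c] for c in self.class_names)
            and all(self.site_total(i) == t for i, t in enumerate(self.published_site_totals))
            and self.grand_total() == self.published_grand_total
        )


PANDA = CohortTable(
    name="PANDA",
    class_names=("positive", "negative"),
    per_site={
        "positive": (1700, 1686, 1800, 1760, 1760),
        "negative": (380, 367, 400, 370, 393),
    },
    published_class_totals={"positive": 8706, "negative": 1910},
    published_site_totals=(2080, 2053, 2200, 2130, 2153),
    published_grand_total=10616,
)

TCGA_NSCLC = CohortTable(
    name="TCGA-NSCLC",
    class_names=("LUAD", "LUSC"),
    per_site={
        "LUAD": (167, 178, 186),
        "LUSC": (180, 168, 164),
    },
    published_class_totals={"LUAD": 531, "LUSC": 512},
    published_site_totals=(347, 346, 350),
    published_grand_total=1043,
)
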