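"""Code taxonomy for end-of-pregnancy events.

Pregnancy-loss codes are organised in three categories according to what the
code and its free-text descriptor suggest about the loss:

* category 1 — suggestive of miscarriage (spontaneous abortion);
* category 2 — suggestive of termination of pregnancy (TOP);
* category 3 — unspecified abortion, not distinguishable from a TOP.

Each category is split into subcategories keyed by the descriptor wording
(``1.1`` ... ``3.4``); subcategory ``3.4`` is the catch-all for loss codes
that match nothing more specific.  The bundled default taxonomy is a toy
code map with one code per subcategory — real ICPC-2/ICD-9 dictionaries are
out of scope — plus the non-loss end-of-pregnancy codes (delivery,
stillbirth, ectopic) and the LMP marker code used to time pregnancies.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CodeTaxonomy",
    "default_taxonomy",
    "LMP_CODE",
    "DELIVERY_CODE",
    "STILLBIRTH_CODE",
    "ECTOPIC_CODE",
    "NON_LOSS_OUTCOME_CODES",
    "SUBCATEGORIES",
    "FALLBACK_SUBCATEGORY",
]

#: marker code whose event date is the recorded last menstrual period
LMP_CODE = "LMP"

DELIVERY_CODE = "W90"
STILLBIRTH_CODE = "W91"
ECTOPIC_CODE = "W80"

NON_LOSS_OUTCOME_CODES = {
    DELIVERY_CODE: "delivery_postpartum",
    STILLBIRTH_CODE: "stillbirth",
    ECTOPIC_CODE: "ectopic",
}

SUBCATEGORIES = (
    "1.1", "1.2", "1.3", "1.4",
    "2.1", "2.2",
    "3.1", "3.2", "3.3", "3.4",
)

#: subcategory for loss events whose code/descriptor matches nothing specific
FALLBACK_SUBCATEGORY = "3.4"

_DEFAULT_ROWS = [
    # code, descriptor_pattern, category, subcategory
    ("W82A", "spontaneous abortion", 1, "1.1"),
    ("W82B", "completed abortion", 1, "1.2"),
    ("W82C", "non-specified completed abortion", 1, "1.3"),
    ("W82D", "curettage process", 1, "1.4"),
    ("W83A", "termination of pregnancy", 2, "2.1"),
    ("W83B", "legal abortion", 2, "2.2"),
    ("W82E", "abortion", 3, "3.1"),
    ("W82F", "abortion on going", 3, "3.2"),
    ("W82G", "complicated abortion", 3, "3.3"),
    ("W82H", "pregnancy loss, other", 3, "3.4"),
]


class TaxonomyError(ValueError):
    """Raised when a taxonomy table violates its structural invariants."""


@dataclass(frozen=True)
class CodeTaxonomy:
    """Lookup table mapping loss codes/descriptors to (category, subcategory).

    Parameters
    ----------
    table
        DataFrame with columns ``code``, ``descriptor_pattern``,
        ``category`` (1, 2 or 3) and ``subcategory`` (one of
        :data:`SUBCATEGORIES`).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"code", "descriptor_pattern", "category", "subcategory"}
        missing = required - set(self.table.columns)
        if missing:
            raise TaxonomyError(f"taxonomy table missing columns: {sorted(missing)}")
        if self.table["code"].duplicated().any():
            dupes = self.table.loc[self.table["code"].duplicated(), "code"].tolist()
            raise TaxonomyError(f"codes mapped to more than one subcategory: {dupes}")
        for _, row in self.table.iterrows():
            sub = str(row["subcategory"])
            if sub not in SUBCATEGORIES:
                raise TaxonomyError(f"unknown subcategory {sub!r}")
            if not sub.startswith(f"{int(row['category'])}."):
                raise TaxonomyError(
                    f"subcategory {sub} inconsistent with category {row['category']}"
                )

    @property
    def loss_codes(self) -> set[str]:
        return set(self.table["code"])

    def category_of(self, subcategory: str) -> int:
        return int(str(subcategory).split(".", 1)[0])

    def subcategory_for_code(self, code: str) -> str | None:
        hit = self.table.loc[self.table["code"] == code, "subcategory"]
        return None if hit.empty else str(hit.iloc[0])

    def subcategory_for_descriptor(self, descriptor: str) -> str | None:
        """Case-insensitive substring match, most specific pattern first.

        Patterns are tried longest-first so that e.g. "spontaneous abortion"
        wins over the bare "abortion" pattern.
        """
        text = " ".join(str(descriptor).lower().split())
        rows = sorted(
            self.table.itertuples(index=False),
            key=lambda r: len(r.descriptor_pattern),
            reverse=True,
        )
        for row in rows:
            if row.descriptor_pattern.lower() in text:
                return str(row.subcategory)
        return None

    @classmethod
    def from_csv(cls, path) -> "CodeTaxonomy":
        return cls(pd.read_csv(path, dtype={"code": str, "subcategory": str}))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def default_taxonomy() -> CodeTaxonomy:
    """Bundled toy taxonomy: one code per loss subcategory."""
    table = pd.DataFrame(
        _DEFAULT_ROWS,
        columns=["code", "descriptor_pattern", "category", "subcategory"],
    )
    return CodeTaxonomy(table)
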