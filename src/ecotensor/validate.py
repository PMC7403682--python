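"""Schema and consistency validation for the tabular inputs."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

FIELD_COLUMNS = ["habitat", "block", "generation", "cross_type", "family",
                 "emergence", "establishment", "maturity"]
TRAIT_META_COLUMNS = ["generation", "group", "family"]


@dataclass
class ValidationReport:
    path: str
    schema: str
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, kind: str, message: str, row: int | None = None) -> None:
        v = {"kind": kind, "message": message}
        if row is not None:
            v["row"] = int(row)
        self.violations.append(v)


def _validate_field(df: pd.DataFrame, rep: ValidationReport) -> None:
    for col in FIELD_COLUMNS:
        if col not in df.columns:
            rep.add("schema", f"missing column `{col}`")
    if rep.violations:
        return
    for col in ("emergence", "establishment", "maturity"):
        bad = ~df[col].isin([0, 1])
        for i in df.index[bad][:20]:
            rep.add("coding", f"non-binary value in `{col}`", row=i)
    est_no_em = (df["establishment"] == 1) & (df["emergence"] == 0)
    mat_no_est = (df["maturity"] == 1) & (df["establishment"] == 0)
    for i in df.index[est_no_em][:20]:
        rep.add("monotonicity", "establishment = 1 but emergence = 0", row=i)
    for i in df.index[mat_no_est][:20]:
        rep.add("monotonicity", "maturity = 1 but establishment = 0", row=i)
    # nesting: a block id must not appear in two habitats, a family id must
    # not appear in two categories
    blk = df.groupby("block")["habitat"].nunique()
    for b in blk[blk > 1].index:
        rep.add("nesting", f"block `{b}` appears in multiple habitats")
    fam = df.groupby("family")["cross_type"].nunique()
    for f in fam[fam > 1].index:
        rep.add("nesting", f"family `{f}` appears in multiple categories")


def _validate_traits(df: pd.DataFrame, rep: ValidationReport) -> None:
    for col in TRAIT_META_COLUMNS:
        if col not in df.columns:
            rep.add("schema", f"missing column `{col}`")
    numeric = df.select_dtypes("number")
    if numeric.shape[1] < 1:
        rep.add("schema", "no numeric trait columns found")
    nmiss = int(numeric.isna().sum().sum())
    if nmiss:
        rep.add("missing", f"{nmiss} missing trait values")


def validate_dataset(path, schema_name: str) -> ValidationReport:
    """Check a CSV against the `field` or `traits` header/consistency contract."""
    p = Path(path)
    rep = ValidationReport(str(p), schema_name)
    if not p.exists():
        raise FileNotFoundError(p)
    try:
        df = pd.read_csv(p)
    except Exception as exc:  # unreadable file
        raise OSError(f"could not read {p}: {exc}") from exc
    if schema_name == "field":
        _validate_field(df, rep)
    elif schema_name == "traits":
        _validate_traits(df, rep)
    else:
        raise ValueError(f"unknown schema {schema_name!r}")
    return rep
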