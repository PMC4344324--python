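"""CSV readers and writers with fixed, documented column layouts.

All tables are UTF-8, comma-separated, '.' decimal, one header row,
preceded by a ``#``-prefixed schema line so a reader can recognize the
table kind and version without guessing. Readers skip comment lines, so
the files also load with plain ``pandas.read_csv(..., comment='#')``.

Layouts
-------
expression   genes as rows (index ``gene``), arrays as columns
design       array_id, day, replicate
cq           gene, sample, tech_rep, cq
droplets     well, target, sample, day, replicate, n_total, n_positive, is_ntc
truth        gene, class, abundance_d<day>...
quant        well, target, sample, day, replicate, lambda, conc,
             ci_low, ci_high, conc_bg[, copies_per_ng]
stability    gene, m_value, rank
vseries      n, v
cv_report    target, day, combo, cv_raw, cv_norm, cv_reduce_pct
profiles     target, day[, replicate], raw_fold, norm_fold
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

SCHEMA_VERSION = 1


def _write(df: pd.DataFrame, path: str | Path, table: str, index: bool) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# refnorm schema={SCHEMA_VERSION} table={table}\n")
        df.to_csv(fh, index=index)


def _read(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def write_expression(expr: pd.DataFrame, path) -> None:
    _write(expr.rename_axis("gene"), path, "expression", index=True)


def read_expression(path) -> pd.DataFrame:
    return _read(path, index_col="gene")


def write_design(design: pd.DataFrame, path) -> None:
    out = design.rename(columns={"sample": "array_id"})
    _write(out[["array_id", "day", "replicate"]], path, "design", index=False)


def read_design(path) -> pd.DataFrame:
    return _read(path).rename(columns={"array_id": "sample"})


def write_cq(cq: pd.DataFrame, path) -> None:
    _write(cq[["gene", "sample", "tech_rep", "cq"]], path, "cq", index=False)


def read_cq(path) -> pd.DataFrame:
    return _read(path)


def write_droplets(wells: pd.DataFrame, path) -> None:
    cols = ["well", "target", "sample", "day", "replicate",
            "n_total", "n_positive", "is_ntc"]
    extra = [c for c in wells.columns if c not in cols]
    _write(wells[cols + extra], path, "droplets", index=False)


def read_droplets(path) -> pd.DataFrame:
    df = _read(path)
    df["is_ntc"] = df["is_ntc"].astype(bool)
    return df


def write_truth(truth, path) -> None:
    df = truth.trajectories.add_prefix("abundance_d")
    df.insert(0, "class", truth.classes)
    _write(df.rename_axis("gene"), path, "truth", index=True)


def write_quant(quant: pd.DataFrame, path) -> None:
    _write(quant, path, "quant", index=False)


def read_quant(path) -> pd.DataFrame:
    return _read(path)


def write_stability(m_values: pd.Series, ranks: pd.Series, path) -> None:
    df = pd.DataFrame({"m_value": m_values, "rank": ranks}).rename_axis("gene")
    _write(df, path, "stability", index=True)


def write_vseries(v: pd.Series, path) -> None:
    _write(v.rename("v").rename_axis("n").reset_index(), path, "vseries",
           index=False)


def write_cv_report(cv_table: pd.DataFrame, path) -> None:
    _write(cv_table, path, "cv_report", index=False)


def write_profiles(profiles: pd.DataFrame, path) -> None:
    _write(profiles, path, "profiles", index=False)
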