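"""Readers, writers and summaries for the pipeline's on-disk artifacts.

In-memory conventions
---------------------
* Expression matrix: :class:`pandas.DataFrame`, genes in rows (index =
  unique symbols), samples in columns, finite non-negative values on the
  platform-native scale (counts or intensities).
* Survival table: :class:`pandas.DataFrame` indexed by sample id with
  columns ``time`` (months) and ``status`` (1 = death), plus optional
  clinical covariates (``age``, ``gender``, ``t_stage``, ``n_stage``,
  ``m_stage``, ``grade``).
* Gene list: a plain ``set`` of symbols.
* Signature: :class:`GenePairSignature`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.44
MONTHS_PER_YEAR = 12.0

CLINICAL_CATEGORICALS = ("gender", "t_stage", "n_stage", "m_stage", "grade")


# ---------------------------------------------------------------------------
# expression matrices


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check expression-matrix invariants, returning the input unchanged."""
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene symbols: {dups[:5]}")
    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dups[:5]}")
    values = expr.to_numpy()
    if values.size and not np.isfinite(values).all():
        raise ValidationError("expression matrix contains non-finite values")
    if values.size and (values < 0).any():
        raise ValidationError("expression matrix contains negative values")
    return expr


def collapse_duplicate_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Average rows sharing a gene symbol (duplicate microarray probes).

    Row order follows the first occurrence of each symbol. Averaging is the
    arithmetic mean on the native scale, applied before any log transform.
    Idempotent on matrices without duplicate symbols.
    """
    if not expr.index.has_duplicates:
        return expr
    order = expr.index[~expr.index.duplicated()]
    collapsed = expr.groupby(level=0, sort=False).mean()
    return collapsed.loc[order]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    samples = header.split(sep)[1:]
    if len(samples) != len(set(samples)):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ParseError(f"{path}: duplicate sample ids in header: {dups}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    return df

def read_expression(path: str | Path, collapse: str = "mean") -> pd.DataFrame:
    """Read a genes x samples TSV/CSV, collapsing duplicate symbols by mean.

    The first column holds gene/probe symbols, the header holds sample ids.
    ``collapse`` currently supports only ``"mean"``.
    """
    if collapse != "mean":
        raise ValueError(f"unsupported collapse strategy: {collapse!r}")
    df = _read_table(path)
    if df.empty and len(df.columns) == 0:
        raise ParseError(f"{path}: no sample columns found")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate sample ids in header: {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[row, col]!r} at "
            f"row {df.index[row]!r}, column {df.columns[col]!r}"
        )
    if numeric.isna().to_numpy().any():
        row, col = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: missing value at row {df.index[row]!r}, "
            f"column {df.columns[col]!r}"
        )
    numeric.index = numeric.index.astype(str)
    collapsed = collapse_duplicate_genes(numeric)
    if len(collapsed) < len(numeric):
        logger.info(
            "collapsed %d probe rows into %d gene rows",
            len(numeric), len(collapsed),
        )
    return validate_expression(collapsed)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# survival tables


def validate_survival(surv: pd.DataFrame) -> pd.DataFrame:
    if surv.index.has_duplicates:
        raise ValidationError("duplicate sample ids in survival table")
    if (surv["time"] <= 0).any():
        bad = surv.index[surv["time"] <= 0].tolist()
        raise ValidationError(f"non-positive follow-up time for samples {bad[:5]}")
    if not surv["status"].isin([0, 1]).all():
        bad = surv.index[~surv["status"].isin([0, 1])].tolist()
        raise ValidationError(f"status outside {{0,1}} for samples {bad[:5]}")
    return surv


def read_survival(path: str | Path, time_unit: str = "months") -> pd.DataFrame:
    """Read a clinical TSV with columns sample_id, time, status [+covariates].

    Times are converted to months (12 months/year, 30.44 days/month).
    Rows with missing time or status are dropped; the count is logged.
    """
    factors = {"months": 1.0, "years": MONTHS_PER_YEAR, "days": 1.0 / DAYS_PER_MONTH}
    if time_unit not in factors:
        raise ValueError(f"time_unit must be one of {sorted(factors)}")
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    for col in ("sample_id", "time", "status"):
        if col not in df.columns:
            raise ParseError(f"{path}: required column {col!r} missing")
    df["time"] = pd.to_numeric(df["time"], errors="coerce")
    df["status"] = pd.to_numeric(df["status"], errors="coerce")
    keep = df["time"].notna() & df["status"].notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d rows with missing time/status", n_dropped)
    df = df.loc[keep].copy()
    df["time"] = df["time"] * factors[time_unit]
    df = df.set_index("sample_id")
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
    return validate_survival(df)


def write_survival(surv: pd.DataFrame, path: str | Path) -> None:
    surv.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# gene lists


def read_gene_list(path: str | Path) -> set[str]:
    """Plain-text gene list, one symbol per line; blank lines ignored."""
    symbols = [ln.strip() for ln in Path(path).read_text().splitlines()]
    symbols = [s for s in symbols if s]
    if not symbols:
        raise ParseError(f"{path}: gene list is empty")
    return set(symbols)


def write_gene_list(genes: set[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# gene-pair signatures


@dataclass
class GenePairSignature:
    """An ordered list of gene pairs with Cox/LASSO coefficients.

    The risk score of a sample is ``sum_k coef_k * indicator_k`` where
    ``indicator_k`` is 1 when the first gene of pair *k* out-expresses the
    second within that sample. Because only within-sample ranks enter, the
    signature transfers across platforms without renormalization.
    """

    pairs: list[tuple[str, str]]
    coefficients: np.ndarray
    cutoff: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.pairs) != len(self.coefficients):
            raise ValidationError("pairs and coefficients differ in length")
        if not np.isfinite(self.coefficients).all():
            raise ValidationError("non-finite coefficient")
        seen = set()
        for a, b in self.pairs:
            if a == b:
                raise ValidationError(f"pair with identical genes: {a}")
            if (a, b) in seen:
                raise ValidationError(f"duplicate pair: {a}|{b}")
            seen.add((a, b))

    @property
    def genes(self) -> set[str]:
        return {g for pair in self.pairs for g in pair}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenePairSignature):
            return NotImplemented
        return (
            self.pairs == other.pairs
            and np.allclose(self.coefficients, other.coefficients, atol=5e-7)
            and (self.cutoff is None) == (other.cutoff is None)
            and (self.cutoff is None or abs(self.cutoff - other.cutoff) < 5e-7)
        )


def read_signature(path: str | Path) -> GenePairSignature:
    """Read a signature from JSON or 3-column TSV (gene_a, gene_b, coefficient)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        pairs, coefs = [], []
        for entry in payload["pairs"]:
            pairs.append((str(entry["gene_a"]), str(entry["gene_b"])))
            coefs.append(float(entry["coefficient"]))
        return GenePairSignature(
            pairs=pairs,
            coefficients=np.array(coefs),
            cutoff=payload.get("cutoff"),
            metadata=payload.get("metadata", {}),
        )
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_a", "gene_b", "coefficient"):
        if col not in df.columns:
            raise ParseError(f"{path}: required column {col!r} missing")
    coefs = pd.to_numeric(df["coefficient"], errors="coerce")
    if coefs.isna().any():
        bad = df.loc[coefs.isna(), "coefficient"].iloc[0]
        raise ParseError(f"{path}: unparseable coefficient {bad!r}")
    return GenePairSignature(
        pairs=list(zip(df["gene_a"].astype(str), df["gene_b"].astype(str))),
        coefficients=coefs.to_numpy(),
    )


def write_signature(sig: GenePairSignature, path: str | Path) -> None:
    """Write a signature as JSON (``.json``) or 3-column TSV, 6 decimals."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "pairs": [
                {"gene_a": a, "gene_b": b, "coefficient": round(float(c), 6)}
                for (a, b), c in zip(sig.pairs, sig.coefficients)
            ],
            "cutoff": sig.cutoff,
            "metadata": sig.metadata,
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    lines = ["gene_a\tgene_b\tcoefficient"]
    for (a, b), c in zip(sig.pairs, sig.coefficients):
        lines.append(f"{a}\t{b}\t{c:.6f}")
    path.write_text("\n".join(lines) + "\n")


def signature_summary(sig: GenePairSignature) -> dict:
    """Pair/gene counts and coefficient extremes of a signature."""
    return {
        "n_pairs": len(sig.pairs),
        "n_unique_genes": len(sig.genes),
        "min_coef": float(sig.coefficients.min()),
        "max_coef": float(sig.coefficients.max()),
    }


def load_bundled_signature() -> GenePairSignature:
    """The published 22-pair head-and-neck signature shipped with the package."""
    ref = _importlib_resources.files("pairrank.resources") / "hnscc_irgp22.tsv"
    with _importlib_resources.as_file(ref) as p:
        return read_signature(p)


def load_bundled_cohort_counts() -> dict:
    """Published per-group clinical counts for the training cohort (counts only)."""
    ref = _importlib_resources.files("pairrank.resources") / "hnscc_cohort_counts.json"
    return json.loads(ref.read_text())


# ---------------------------------------------------------------------------
# cohort summary tables


def cohort_from_counts(counts: dict) -> tuple[pd.DataFrame, pd.Series]:
    """Expand a stratified count table into a per-sample frame + group labels.

    The inverse of :func:`cohort_table` for categorical variables: given
    ``{"groups": {label: {"n": N, var: {level: count, ...}, ...}}}``,
    materialize one row per subject with the stated level assignments
    ("Missing" counts become NaN). Follow-up columns are placeholders.
    """
    frames = []
    labels = []
    for g, spec in counts["groups"].items():
        n = int(spec["n"])
        frame = pd.DataFrame(index=pd.RangeIndex(n))
        for var, level_counts in spec.items():
            if var == "n":
                continue
            values: list = []
            for level, count in level_counts.items():
                fill = np.nan if level == "Missing" else level
                values.extend([fill] * int(count))
            if len(values) != n:
                raise ValidationError(
                    f"group {g!r}, variable {var!r}: counts sum to "
                    f"{len(values)}, expected {n}"
                )
            frame[var] = values
        frame["time"] = 1.0
        frame["status"] = 0
        frame.index = [f"{g}{i + 1:04d}" for i in range(n)]
        frames.append(frame)
        labels.extend([g] * n)
    surv = pd.concat(frames)
    surv.index.name = "sample_id"
    return surv, pd.Series(labels, index=surv.index, name="group")


def format_count_pct(count: int, total: int) -> str:
    """``"214 (74.8%)"`` — count with within-group percentage, 1 decimal."""
    pct = 0.0 if total == 0 else 100.0 * count / total
    return f"{count} ({pct:.1f}%)"


def cohort_table(
    surv: pd.DataFrame,
    groups: pd.Series,
    categoricals: tuple[str, ...] = CLINICAL_CATEGORICALS,
) -> pd.DataFrame:
    """Stratified clinical summary in the style of a cohort-characteristics table.

    One column per group. Age rows report mean/median/min/max; each
    categorical covariate gets one row per level plus an explicit
    ``Missing`` row, formatted ``"count (pct%)"`` with within-group
    percentages to one decimal.
    """
    unknown = groups.index.difference(surv.index)
    if len(unknown):
        raise ValidationError(f"groups contain unknown samples: {unknown[:5].tolist()}")
    if not surv.index.isin(groups.index).all():
        missing = surv.index.difference(groups.index)
        raise ValidationError(f"groups missing for samples: {missing[:5].tolist()}")
    groups = groups.loc[surv.index]
    rows: dict[tuple[str, str], dict[str, str]] = {}
    group_levels = list(pd.unique(groups))
    for g in group_levels:
        sub = surv.loc[groups == g]
        n = len(sub)
        rows.setdefault(("N", ""), {})[g] = str(n)
        if "age" in sub.columns and sub["age"].notna().any():
            age = sub["age"].dropna()
            rows.setdefault(("Age", "Mean (SD)"), {})[g] = (
                f"{age.mean():.2f} ({age.std():.2f})"
            )
            rows.setdefault(("Age", "Median (min, max)"), {})[g] = (
                f"{age.median():.0f} ({age.min():.0f}, {age.max():.0f})"
            )
        for var in categoricals:
            if var not in sub.columns:
                continue
            col = sub[var]
            levels = sorted(x for x in surv[var].dropna().unique())
            for level in levels:
                count = int((col == level).sum())
                rows.setdefault((var, str(level)), {})[g] = format_count_pct(count, n)
            n_missing = int(col.isna().sum())
            rows.setdefault((var, "Missing"), {})[g] = format_count_pct(n_missing, n)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["variable", "level"])
    return table[group_levels]
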