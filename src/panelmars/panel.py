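"""Balanced country-by-year panels: I/O, transforms and design matrices.

The data model is a *balanced* panel: every country is observed in every
year, with no missing cells, and the years form one contiguous run shared
by all countries.  Everything downstream (the spline fit, the endogeneity
and causality screens) assumes this, so the constructor enforces it hard
rather than trying to repair gappy input.

The only external data format is a wide CSV with a mandatory header
``country,year,<var1>,...``: ``country`` is a string, ``year`` an integer,
every other column a real number.  Rows are canonicalised to (country
lexicographic, year ascending) order on construction so that every
downstream fit is reproducible byte for byte regardless of input row
order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PanelError",
    "PanelDataset",
    "DesignMatrix",
    "read_panel_csv",
    "write_panel_csv",
    "log_transform",
    "to_design",
    "descriptive_stats",
]


class PanelError(ValueError):
    """Malformed panel data: unbalanced, missing, duplicated or bad cells."""


class PanelDataset:
    """A balanced panel of named real-valued variables.

    Parameters
    ----------
    frame:
        Wide table whose first two columns are ``country`` and ``year``;
        every remaining column is a numeric variable.  One row per
        (country, year).
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        if not isinstance(frame, pd.DataFrame):
            raise PanelError("PanelDataset requires a pandas DataFrame")
        cols = list(frame.columns)
        if cols[:2] != ["country", "year"]:
            raise PanelError(
                "first two columns must be 'country' and 'year', got "
                f"{cols[:2]!r}"
            )
        variables = cols[2:]
        if len(set(variables)) != len(variables):
            raise PanelError("duplicate variable names in header")
        f = frame.copy()
        f["country"] = f["country"].astype(str)
        if any("," in c for c in f["country"]):
            raise PanelError("country names may not contain commas")
        years = pd.to_numeric(f["year"], errors="coerce")
        if years.isna().any() or (years != years.round()).any():
            bad = f.index[years.isna() | (years != years.round())][0]
            raise PanelError(f"non-integer year in row {bad}")
        f["year"] = years.astype(int)
        for v in variables:
            vals = pd.to_numeric(f[v], errors="coerce")
            bad = vals.isna() | ~np.isfinite(vals)
            if bad.any():
                i = f.index[bad][0]
                raise PanelError(
                    f"non-numeric or non-finite cell in row {i}, column {v!r}"
                )
            f[v] = vals.astype(float)

        dup = f.duplicated(subset=["country", "year"])
        if dup.any():
            c, yr = f.loc[f.index[dup][0], ["country", "year"]]
            raise PanelError(f"duplicate (country, year) pair ({c!r}, {yr})")

        f = f.sort_values(["country", "year"], kind="mergesort").reset_index(drop=True)

        year_sets = f.groupby("country")["year"].apply(tuple)
        ref = year_sets.iloc[0]
        for c, ys in year_sets.items():
            if ys != ref:
                raise PanelError(
                    f"unbalanced panel: country {c!r} has years {sorted(set(ys))}, "
                    f"expected {sorted(set(ref))}"
                )
        if len(ref) > 1 and tuple(range(ref[0], ref[-1] + 1)) != ref:
            raise PanelError(f"years are not contiguous: {list(ref)}")

        self._frame = f
        self._variables = list(variables)

    # -- accessors ---------------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        """Canonically ordered copy of the underlying wide table."""
        return self._frame.copy()

    @property
    def countries(self) -> list[str]:
        return list(dict.fromkeys(self._frame["country"]))

    @property
    def years(self) -> list[int]:
        return sorted(set(self._frame["year"]))

    @property
    def variable_names(self) -> list[str]:
        return list(self._variables)

    @property
    def n_rows(self) -> int:
        return len(self._frame)

    @property
    def n_values(self) -> int:
        """Total cell count: countries x years x variables."""
        return len(self._frame) * len(self._variables)

    def value(self, country: str, year: int, var: str) -> float:
        m = (self._frame["country"] == country) & (self._frame["year"] == year)
        if not m.any():
            raise PanelError(f"no row for ({country!r}, {year})")
        if var not in self._variables:
            raise PanelError(f"unknown variable {var!r}")
        return float(self._frame.loc[m, var].iloc[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PanelDataset):
            return NotImplemented
        return self._frame.equals(other._frame)

    def __repr__(self) -> str:
        return (
            f"PanelDataset({len(self.countries)} countries x "
            f"{len(self.years)} years x {len(self._variables)} variables)"
        )


@dataclass
class DesignMatrix:
    """Response vector plus predictor matrix in canonical row order."""

    y: np.ndarray
    X: np.ndarray
    row_index: list[tuple]
    column_names: list[str]
    response_name: str = "y"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise PanelError("X must be 2-dimensional")
        n = self.y.size
        if self.X.shape[0] != n or len(self.row_index) != n:
            raise PanelError("y, X and row_index disagree on the number of rows")
        if self.X.shape[1] != len(self.column_names):
            raise PanelError("X and column_names disagree on the number of columns")
        if len(set(self.column_names)) != len(self.column_names):
            raise PanelError("duplicate predictor names")
        if not np.all(np.isfinite(self.y)) or (
            self.X.size and not np.all(np.isfinite(self.X))
        ):
            raise PanelError("non-finite entries in design")

    @property
    def n(self) -> int:
        return self.y.size

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.column_names.index(name)
        except ValueError:
            raise PanelError(f"unknown predictor {name!r}") from None
        return self.X[:, j]


def read_panel_csv(path) -> PanelDataset:
    """Read a wide-format panel CSV, rejecting unbalanced or malformed input."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(raw.columns)
    if cols[:2] != ["country", "year"]:
        raise PanelError(
            f"header must start with 'country,year', got {','.join(cols[:3])!r}"
        )
    for v in cols[2:]:
        empty = raw[v].str.strip() == ""
        if empty.any():
            i = raw.index[empty][0]
            raise PanelError(f"missing cell in row {i + 2} (column {v!r})")
    return PanelDataset(raw)


def write_panel_csv(ds: PanelDataset, path) -> None:
    """Write a PanelDataset as wide CSV at full (round-trip) precision."""
    f = ds.frame
    lines = [",".join(["country", "year", *ds.variable_names])]
    for _, row in f.iterrows():
        cells = [str(row["country"]), str(int(row["year"]))]
        cells += [repr(float(row[v])) for v in ds.variable_names]
        lines.append(",".join(cells))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def log_transform(ds: PanelDataset, variables: list[str]) -> PanelDataset:
    """Replace the selected variables by their natural logarithms.

    Non-positive values are a hard error (no offset is applied), with the
    offending (country, year, variable) named.
    """
    f = ds.frame
    for v in variables:
        if v not in ds.variable_names:
            raise PanelError(f"unknown variable {v!r}")
        bad = f[v] <= 0.0
        if bad.any():
            row = f.loc[f.index[bad][0]]
            raise PanelError(
                f"cannot log-transform non-positive value {row[v]} at "
                f"({row['country']!r}, {int(row['year'])}, {v!r})"
            )
        f[v] = np.log(f[v].to_numpy())
    return PanelDataset(f)


def to_design(
    ds: PanelDataset, response: str, predictors: list[str]
) -> DesignMatrix:
    """Extract a response vector and predictor matrix in canonical order."""
    names = ds.variable_names
    if response not in names:
        raise PanelError(f"unknown response {response!r}")
    for p in predictors:
        if p not in names:
            raise PanelError(f"unknown predictor {p!r}")
    if response in predictors:
        raise PanelError(f"response {response!r} duplicated in predictors")
    if len(set(predictors)) != len(predictors):
        raise PanelError("duplicate predictor names")
    f = ds.frame
    y = f[response].to_numpy(dtype=float)
    X = (
        f[list(predictors)].to_numpy(dtype=float)
        if predictors
        else np.empty((len(f), 0))
    )
    rows = list(zip(f["country"], (int(v) for v in f["year"])))
    return DesignMatrix(y, X, rows, list(predictors), response_name=response)


def descriptive_stats(ds: PanelDataset) -> pd.DataFrame:
    """Per-variable summary: mean, sd, variance, coef. of variation, min,
    max, range.  The standard deviation uses the sample (n-1) denominator;
    coef_var = 100 * sd / mean; range = max - min."""
    f = ds.frame
    rows = {}
    for v in ds.variable_names:
        x = f[v].to_numpy(dtype=float)
        mean = float(x.mean())
        sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
        rows[v] = {
            "mean": mean,
            "sd": sd,
            "variance": sd**2,
            "coef_var": 100.0 * sd / mean if mean != 0 else np.inf,
            "min": float(x.min()),
            "max": float(x.max()),
            "range": float(x.max() - x.min()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
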