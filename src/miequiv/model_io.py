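"""Measurement-model syntax and group-moment input/output.

A measurement model is written one factor per line as::

    FactorName =~ indicator1 + indicator2 + ...

Group data enter either as raw observation tables (one group-membership
column) or as plain-text moment files: a header row of variable names, a
row labeled ``mean`` holding the sample means, then a labeled covariance
matrix.  Moment files are assumed to carry the unbiased (n-1)-divisor
covariance; they are rescaled to the ML (divisor-n) convention on read,
which is the convention :class:`GroupMoments` stores internally.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "GroupMoments",
    "ModelSyntaxError",
    "MomentFormatError",
    "parse_model",
    "serialize_model",
    "read_moments",
    "write_moments",
    "moments_from_raw",
]


class ModelSyntaxError(ValueError):
    """Raised for malformed or inconsistent model syntax."""


class MomentFormatError(ValueError):
    """Raised for malformed moment files."""


@dataclass(frozen=True)
class ModelSpec:
    """Factor -> indicator map defining the loading-matrix pattern.

    Parameters
    ----------
    factors
        Ordered ``(factor_name, (indicator, ...))`` pairs.
    all_variables
        Ordered tuple of the p distinct indicator names (listing order).
    """

    factors: tuple[tuple[str, tuple[str, ...]], ...]
    all_variables: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.factors:
            raise ModelSyntaxError("model must define at least one factor")
        names = [f for f, _ in self.factors]
        if len(set(names)) != len(names):
            raise ModelSyntaxError("duplicate factor names in model")
        for fname, inds in self.factors:
            if not inds:
                raise ModelSyntaxError(f"factor {fname!r} has no indicators")
            if fname in self.all_variables:
                raise ModelSyntaxError(
                    f"factor name {fname!r} duplicates a variable name"
                )
            for ind in inds:
                if ind not in self.all_variables:
                    raise ModelSyntaxError(
                        f"indicator {ind!r} missing from variable list"
                    )
        if self.n_variables < self.n_factors:
            raise ModelSyntaxError("more factors than variables")

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f for f, _ in self.factors)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def n_variables(self) -> int:
        return len(self.all_variables)

    def loading_pattern(self) -> np.ndarray:
        """Boolean p x k pattern: True where an indicator loads on a factor."""
        p, k = self.n_variables, self.n_factors
        pat = np.zeros((p, k), dtype=bool)
        vidx = {v: i for i, v in enumerate(self.all_variables)}
        for c, (_, inds) in enumerate(self.factors):
            for ind in inds:
                pat[vidx[ind], c] = True
        return pat

    def marker_indices(self) -> tuple[int, ...]:
        """Row index of the first indicator of each factor (fixed loading 1)."""
        vidx = {v: i for i, v in enumerate(self.all_variables)}
        return tuple(vidx[inds[0]] for _, inds in self.factors)

    def cross_loadings(self) -> tuple[tuple[str, tuple[str, ...]], ...]:
        """Indicators loading on more than one factor."""
        owners: dict[str, list[str]] = {}
        for fname, inds in self.factors:
            for ind in inds:
                owners.setdefault(ind, []).append(fname)
        return tuple(
            (v, tuple(fs)) for v, fs in owners.items() if len(fs) > 1
        )


_LINE_RE = re.compile(r"^\s*(?P<lhs>\S+)\s*=~\s*(?P<rhs>.+?)\s*$")


def parse_model(text: str) -> ModelSpec:
    """Parse ``factor =~ a + b`` measurement syntax into a :class:`ModelSpec`."""
    if not text or not text.strip():
        raise ModelSyntaxError("empty model syntax")
    factors: list[tuple[str, tuple[str, ...]]] = []
    variables: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip().strip("'\"")
        if not line:
            continue
        m = _LINE_RE.match(line)
        if m is None or "=~" not in line:
            raise ModelSyntaxError(
                f"line {lineno}: expected 'factor =~ ind1 + ind2', got {raw!r}"
            )
        fname = m.group("lhs")
        inds = tuple(tok.strip() for tok in m.group("rhs").split("+"))
        if any(not tok for tok in inds):
            raise ModelSyntaxError(f"line {lineno}: empty indicator name")
        for ind in inds:
            if ind not in variables:
                variables.append(ind)
        factors.append((fname, inds))
    return ModelSpec(tuple(factors), tuple(variables))


def serialize_model(spec: ModelSpec) -> str:
    """Inverse of :func:`parse_model` (up to whitespace)."""
    return "\n".join(
        f"{fname} =~ " + " + ".join(inds) for fname, inds in spec.factors
    ) + "\n"


@dataclass
class GroupMoments:
    """One group's sample size, mean vector and ML (divisor-n) covariance."""

    label: str
    n: int
    mean: np.ndarray
    cov: np.ndarray
    variables: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = np.asarray(self.cov, dtype=float)
        p = self.mean.size
        if int(self.n) <= 0:
            raise ValueError(f"group {self.label!r}: sample size must be positive")
        self.n = int(self.n)
        if self.cov.shape != (p, p):
            raise MomentFormatError(
                f"group {self.label!r}: covariance is {self.cov.shape}, "
                f"mean has length {p}"
            )
        if not self.variables:
            self.variables = tuple(f"v{i + 1}" for i in range(p))
        asym = np.abs(self.cov - self.cov.T)
        scale = max(np.abs(self.cov).max(), 1.0)
        if asym.max() > 1e-8 * scale:
            raise ValueError(
                f"group {self.label!r}: covariance asymmetric beyond tolerance"
            )
        self.cov = (self.cov + self.cov.T) / 2.0
        eigmin = np.linalg.eigvalsh(self.cov).min()
        if eigmin < -1e-8 * scale:
            raise ValueError(
                f"group {self.label!r}: covariance not positive semidefinite "
                f"(min eigenvalue {eigmin:.3g})"
            )

    @property
    def p(self) -> int:
        return self.mean.size


def _tokenize(line: str) -> list[str]:
    if "," in line:
        return [t.strip() for t in line.split(",")]
    return line.split()


def read_moments(path_or_buf, n: int, label: str | None = None) -> GroupMoments:
    """Read one group's moment file.

    The file holds a header of variable names, a ``mean``-labeled row and a
    labeled covariance matrix.  The covariance is assumed (n-1)-based and is
    rescaled by (n-1)/n to the ML convention.  ``n`` is supplied by the
    caller; it is not part of the file dialect.
    """
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf, "r", encoding="utf-8") as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 3:
        raise MomentFormatError("moment file needs header, mean row and covariance")
    header = _tokenize(lines[0])
    if header and header[0] == "":
        header = header[1:]
    variables = tuple(header)
    p = len(variables)
    if p == 0:
        raise MomentFormatError("no variable names in header")

    mean_toks = _tokenize(lines[1])
    if not mean_toks or mean_toks[0].lower() != "mean":
        raise MomentFormatError("second row must be labeled 'mean'")
    if len(mean_toks) != p + 1:
        raise MomentFormatError(
            f"mean row has {len(mean_toks) - 1} values, expected {p}"
        )
    try:
        mean = np.array([float(t) for t in mean_toks[1:]])
    except ValueError as exc:
        raise MomentFormatError(f"non-numeric mean value: {exc}") from None

    cov_lines = lines[2:]
    if len(cov_lines) != p:
        raise MomentFormatError(
            f"covariance block has {len(cov_lines)} rows, expected {p} (non-square)"
        )
    cov = np.empty((p, p))
    for i, ln in enumerate(cov_lines):
        toks = _tokenize(ln)
        if len(toks) != p + 1:
            raise MomentFormatError(
                f"covariance row {i + 1} has {len(toks) - 1} values, expected {p}"
            )
        if toks[0] != variables[i]:
            raise MomentFormatError(
                f"covariance row {i + 1} labeled {toks[0]!r}, expected "
                f"{variables[i]!r}"
            )
        try:
            cov[i] = [float(t) for t in toks[1:]]
        except ValueError as exc:
            raise MomentFormatError(
                f"non-numeric covariance value in row {i + 1}: {exc}"
            ) from None

    n = int(n)
    cov_ml = cov * (n - 1) / n if n > 1 else cov
    return GroupMoments(
        label=label or "group", n=n, mean=mean, cov=cov_ml, variables=variables
    )


def write_moments(gm: GroupMoments, path_or_buf=None, fmt: str = "%.10g") -> str:
    """Write a moment file in the dialect read by :func:`read_moments`.

    Emits the (n-1)-based covariance (inverse of the rescaling applied on
    read) so that read/write round-trips are lossless.
    """
    n = gm.n
    cov = gm.cov * n / (n - 1) if n > 1 else gm.cov
    buf = io.StringIO()
    buf.write(" " + " ".join(gm.variables) + "\n")
    buf.write("mean " + " ".join(fmt % v for v in gm.mean) + "\n")
    for i, v in enumerate(gm.variables):
        buf.write(v + " " + " ".join(fmt % x for x in cov[i]) + "\n")
    text = buf.getvalue()
    if path_or_buf is not None:
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w", encoding="utf-8") as fh:
                fh.write(text)
    return text


def moments_from_raw(
    table: pd.DataFrame | str,
    group_col: str,
    variables: Sequence[str] | None = None,
) -> list[GroupMoments]:
    """Split a raw observation table by group and compute sample moments.

    The unbiased (n-1) covariance is computed first and rescaled by
    (n-1)/n, i.e. the stored covariance uses the divisor-n ML convention.
    Groups are ordered by first appearance.
    """
    if isinstance(table, (str, bytes)) or hasattr(table, "__fspath__"):
        table = pd.read_csv(table)
    if group_col not in table.columns:
        raise KeyError(f"group column {group_col!r} not in table")
    if variables is None:
        variables = [c for c in table.columns if c != group_col]
    for c in variables:
        col = pd.to_numeric(table[c], errors="coerce")
        bad = col.isna() & table[c].notna()
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value in column {c!r} at row {idx}"
            )
        if col.isna().any():
            idx = int(np.flatnonzero(col.isna().to_numpy())[0])
            raise ValueError(f"missing value in column {c!r} at row {idx}")

    labels = table[group_col].tolist()
    seen: list = []
    for lab in labels:
        if lab not in seen:
            seen.append(lab)
    if len(seen) < 2:
        raise ValueError("need at least two distinct group labels")

    out: list[GroupMoments] = []
    p = len(variables)
    for lab in seen:
        sub = table.loc[table[group_col] == lab, list(variables)].to_numpy(float)
        n = sub.shape[0]
        if n <= p:
            import warnings

            warnings.warn(
                f"group {lab!r}: n={n} <= p={p}, sample covariance is singular",
                RuntimeWarning,
                stacklevel=2,
            )
        mean = sub.mean(axis=0)
        centered = sub - mean
        cov_unb = centered.T @ centered / max(n - 1, 1)
        var = np.diag(cov_unb)
        if np.any(var <= 0):
            j = int(np.argmin(var))
            raise ValueError(
                f"variable {variables[j]!r} has zero variance in group {lab!r}"
            )
        cov_ml = cov_unb * (n - 1) / n
        out.append(
            GroupMoments(
                label=str(lab), n=n, mean=mean, cov=cov_ml,
                variables=tuple(variables),
            )
        )
    return out
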