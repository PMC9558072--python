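"""Domain types and file I/O.

The objects here carry the data the rest of the package consumes: a
gene-by-sample expression matrix, a per-sample clinical table (survival time,
event indicator, treatment-response label, covariates), ordered gene pairs and
gene-pair signatures.

Everything downstream of the expression matrix consumes only the *within-sample
relative ordering* of genes (which of two genes is expressed higher inside one
sample), so the expression scale is deliberately unconstrained: microarray
intensities, RNA-seq quantifications, log- or linear-scale values are all
acceptable as long as values within a sample are mutually comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "GenePair",
    "StratRule",
    "Signature",
    "ExpressionMatrix",
    "ClinicalTable",
    "load_expression",
    "load_clinical",
    "load_gene_list",
    "load_signature",
    "save_signature",
    "ips_signature",
    "RESPONDER",
    "NON_RESPONDER",
]

RESPONDER = "responder"
NON_RESPONDER = "non_responder"


class ParseError(ValueError):
    """A file could not be interpreted (malformed cell, missing column)."""


class ValidationError(ValueError):
    """An input violated a domain invariant."""


def _norm(symbol: str) -> str:
    """Case-insensitive matching key for a gene symbol."""
    return symbol.strip().casefold()


@dataclass(frozen=True)
class GenePair:
    """Ordered gene pair; its per-sample score is 1 iff expr[gene_a] > expr[gene_b].

    Ties score 0 — a pair is "on" only when the first member is strictly the
    higher-expressed of the two.
    """

    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        a, b = self.gene_a.strip(), self.gene_b.strip()
        if not a or not b:
            raise ValidationError("gene pair members must be non-empty symbols")
        if _norm(a) == _norm(b):
            raise ValidationError(f"gene pair members must differ, got ({a!r}, {b!r})")
        object.__setattr__(self, "gene_a", a)
        object.__setattr__(self, "gene_b", b)

    @property
    def key(self) -> tuple[str, str]:
        return (_norm(self.gene_a), _norm(self.gene_b))

    def __str__(self) -> str:
        return f"{self.gene_a}>{self.gene_b}"


@dataclass(frozen=True)
class StratRule:
    """Patient stratification rule for a signature score.

    ``median``: high iff score strictly exceeds the cohort median.
    ``fixed_threshold``: high iff score strictly exceeds ``threshold``
    (the published 18-pair signature uses threshold 9, i.e. score > 9 -> high).
    """

    kind: Literal["median", "fixed_threshold"]
    threshold: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("median", "fixed_threshold"):
            raise ValidationError(f"unknown stratification rule {self.kind!r}")
        if self.kind == "fixed_threshold":
            if self.threshold is None or int(self.threshold) != self.threshold:
                raise ValidationError("fixed_threshold rule requires an integer threshold")
            object.__setattr__(self, "threshold", int(self.threshold))
        elif self.threshold is not None:
            raise ValidationError("median rule takes no threshold")

    @classmethod
    def parse(cls, text: str) -> "StratRule":
        """Parse ``"median"`` or ``"threshold:<int>"``."""
        text = text.strip()
        if text == "median":
            return cls("median")
        if text.startswith("threshold:"):
            return cls("fixed_threshold", int(text.split(":", 1)[1]))
        raise ValidationError(f"cannot parse stratification rule {text!r}")

    def to_dict(self) -> dict:
        if self.kind == "median":
            return {"strat_rule": "median"}
        return {"strat_rule": {"fixed_threshold": self.threshold}}

    @classmethod
    def from_dict(cls, obj) -> "StratRule":
        if isinstance(obj, dict) and "strat_rule" in obj:
            obj = obj["strat_rule"]
        if obj == "median" or obj == {"median": True}:
            return cls("median")
        if isinstance(obj, dict) and "fixed_threshold" in obj:
            return cls("fixed_threshold", obj["fixed_threshold"])
        raise ValidationError(f"cannot interpret stratification rule {obj!r}")


@dataclass(frozen=True)
class Signature:
    """An ordered list of gene pairs plus a stratification rule.

    A sample's signature score is the number of pairs scoring 1, an integer in
    [0, len(pairs)].
    """

    pairs: tuple[GenePair, ...]
    strat_rule: StratRule = field(default_factory=lambda: StratRule("median"))

    def __post_init__(self) -> None:
        pairs = tuple(self.pairs)
        if not pairs:
            raise ValidationError("signature must contain at least one pair")
        keys = [p.key for p in pairs]
        if len(set(keys)) != len(keys):
            dup = [k for k in keys if keys.count(k) > 1][0]
            raise ValidationError(f"duplicate ordered pair in signature: {dup[0]}>{dup[1]}")
        object.__setattr__(self, "pairs", pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def genes(self) -> list[str]:
        """Distinct gene symbols, in first-appearance order."""
        seen: dict[str, str] = {}
        for p in self.pairs:
            for g in (p.gene_a, p.gene_b):
                seen.setdefault(_norm(g), g)
        return list(seen.values())


class ExpressionMatrix:
    """Gene-by-sample matrix of finite expression values.

    Gene symbols are matched case-insensitively after whitespace trimming; the
    original spelling of the first occurrence is preserved.
    """

    def __init__(self, data: pd.DataFrame, *, copy: bool = True):
        if copy:
            data = data.copy()
        data.index = [str(g).strip() for g in data.index]
        data.columns = [str(s).strip() for s in data.columns]
        if data.shape[0] < 2 or data.shape[1] < 2:
            raise ValidationError(
                f"expression matrix needs >=2 genes and >=2 samples, got {data.shape}"
            )
        keys = [_norm(g) for g in data.index]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate gene symbols (collapse duplicates on load)")
        if len(set(data.columns)) != len(data.columns):
            raise ValidationError("duplicate sample identifiers")
        values = data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("expression values must all be finite")
        self.data = data.astype(float)
        self._lookup = {k: label for k, label in zip(keys, data.index)}

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def has_gene(self, symbol: str) -> bool:
        return _norm(symbol) in self._lookup

    def resolve_genes(self, symbols: Iterable[str]) -> tuple[list[str], list[str]]:
        """Map symbols to the matrix's own spellings; returns (found, missing)."""
        found, missing = [], []
        for s in symbols:
            label = self._lookup.get(_norm(s))
            (found if label is not None else missing).append(label if label is not None else s)
        return found, missing

    def row(self, symbol: str) -> np.ndarray:
        label = self._lookup.get(_norm(symbol))
        if label is None:
            raise KeyError(symbol)
        return self.data.loc[label].to_numpy()

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


def load_expression(path, collapse: Literal["max", "first"] = "max") -> ExpressionMatrix:
    """Read a gene-by-sample TSV (first column = gene id, remaining columns samples).

    Duplicate gene rows (case-insensitive) are collapsed per ``collapse``:
    ``max`` keeps the element-wise maximum across duplicate rows, ``first``
    keeps the first row encountered. Non-numeric cells raise :class:`ParseError`
    naming the offending gene and sample.
    """
    if collapse not in ("max", "first"):
        raise ValidationError(f"unknown collapse policy {collapse!r}")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 3:
        raise ValidationError(
            f"{path}: expression file needs a gene column and >=2 sample columns"
        )
    gene_col = raw.columns[0]
    genes = raw[gene_col].astype(str).str.strip()
    numeric = {}
    for col in raw.columns[1:]:
        converted = pd.to_numeric(raw[col].str.strip(), errors="coerce")
        bad = converted.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {raw[col].iloc[i]!r} for gene "
                f"{genes.iloc[i]!r} in sample column {col!r}"
            )
        numeric[col] = converted
    frame = pd.DataFrame(numeric)
    frame.index = list(genes)

    keys = genes.map(_norm)
    if keys.duplicated().any():
        if collapse == "first":
            keep = ~keys.duplicated().to_numpy()
            frame = frame.iloc[keep]
        else:  # max
            spelling = {}
            for k, g in zip(keys, genes):
                spelling.setdefault(k, g)
            frame = frame.groupby(keys.to_numpy(), sort=False).max()
            frame.index = [spelling[k] for k in frame.index]
    return ExpressionMatrix(frame, copy=False)


class ClinicalTable:
    """Per-sample clinical records: survival time (months), event, response, covariates.

    ``time`` must be strictly positive and ``event`` in {0, 1}. The optional
    ``response`` column takes values ``responder`` / ``non_responder`` or is
    missing. Any further columns ride along as covariates.
    """

    REQUIRED = ("time", "event")

    def __init__(self, data: pd.DataFrame, *, copy: bool = True):
        if copy:
            data = data.copy()
        if data.index.name != "sample_id":
            if "sample_id" in data.columns:
                data = data.set_index("sample_id")
            else:
                raise ValidationError("clinical table needs a sample_id column")
        data.index = [str(s).strip() for s in data.index]
        data.index.name = "sample_id"
        for col in self.REQUIRED:
            if col not in data.columns:
                raise ValidationError(f"clinical table missing required column {col!r}")
        if pd.Index(data.index).duplicated().any():
            raise ValidationError("duplicate sample_id in clinical table")

        time = pd.to_numeric(data["time"], errors="coerce")
        if time.isna().any() or (time <= 0).any():
            bad = data.index[time.isna() | (time <= 0)][0]
            raise ValidationError(f"time must be strictly positive (sample {bad!r})")
        event = pd.to_numeric(data["event"], errors="coerce")
        if event.isna().any() or ~event.isin((0, 1)).all():
            bad = data.index[event.isna() | ~event.isin((0, 1))][0]
            raise ValidationError(f"event must be 0 or 1 (sample {bad!r})")
        data["time"] = time.astype(float)
        data["event"] = event.astype(int)

        if "response" in data.columns:
            resp = data["response"].astype(object)
            resp = resp.where(~resp.isin(("", "NA", "nan", None)), other=pd.NA)
            resp = resp.where(~pd.isna(resp), other=pd.NA)
            ok = resp.isin((RESPONDER, NON_RESPONDER)) | resp.isna()
            if not ok.all():
                bad = resp[~ok].iloc[0]
                raise ValidationError(
                    f"response must be {RESPONDER!r}/{NON_RESPONDER!r} or missing, got {bad!r}"
                )
            data["response"] = resp
        self.data = data

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]

    @property
    def response(self) -> pd.Series | None:
        return self.data["response"] if "response" in self.data.columns else None

    @property
    def covariate_names(self) -> list[str]:
        skip = set(self.REQUIRED) | {"response"}
        return [c for c in self.data.columns if c not in skip]

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)])

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t")

    def __repr__(self) -> str:
        return f"ClinicalTable({len(self)} samples, covariates={self.covariate_names})"


def load_clinical(path) -> ClinicalTable:
    """Read a clinical TSV with columns sample_id, time, event [, response, covariates...]."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in raw.columns:
        raise ValidationError(f"{path}: clinical table needs a sample_id column")
    for col in raw.columns:
        if col in ("sample_id", "time", "event", "response"):
            continue
        converted = pd.to_numeric(raw[col], errors="coerce")
        if not converted.isna().any():
            raw[col] = converted
    if "response" in raw.columns:
        raw["response"] = raw["response"].replace("", pd.NA)
    return ClinicalTable(raw)


def load_gene_list(path) -> list[str]:
    """Read a plain-text gene list, one symbol per line; '#' starts a comment."""
    out: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        sym = line.split("#", 1)[0].strip()
        if sym and _norm(sym) not in seen:
            seen.add(_norm(sym))
            out.append(sym)
    return out


def load_signature(path) -> Signature:
    """Read a signature.

    A ``.json`` file holds ``{"pairs": [[gene_a, gene_b], ...], "strat_rule": ...}``.
    Otherwise the file is a TSV with header ``gene_a<TAB>gene_b``; a sidecar
    ``<stem>.json`` (if present) supplies the stratification rule, else the
    median rule applies.
    """
    path = Path(path)
    if path.suffix == ".json":
        obj = json.loads(path.read_text())
        pairs = [GenePair(a, b) for a, b in obj["pairs"]]
        rule = StratRule.from_dict(obj) if "strat_rule" in obj else StratRule("median")
        return Signature(tuple(pairs), rule)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_a" not in raw.columns or "gene_b" not in raw.columns:
        raise ParseError(f"{path}: signature TSV needs gene_a and gene_b columns")
    pairs = tuple(GenePair(a, b) for a, b in zip(raw["gene_a"], raw["gene_b"]))
    sidecar = path.with_suffix(".json")
    rule = StratRule("median")
    if sidecar.exists():
        rule = StratRule.from_dict(json.loads(sidecar.read_text()))
    return Signature(pairs, rule)


def save_signature(sig: Signature, path) -> None:
    """Write a signature TSV plus its stratification-rule JSON sidecar."""
    path = Path(path)
    pd.DataFrame(
        {"gene_a": [p.gene_a for p in sig.pairs], "gene_b": [p.gene_b for p in sig.pairs]}
    ).to_csv(path, sep="\t", index=False)
    path.with_suffix(".json").write_text(json.dumps(sig.strat_rule.to_dict(), indent=2) + "\n")


def ips_signature() -> Signature:
    """The bundled 18-pair immuno-score signature (IPS).

    18 ordered pairs over 24 distinct genes; a patient scores one point per
    pair whose first gene is expressed above its second, and scores above 9
    define the high-score (immune-favourable) group.
    """
    base = resources.files("reoscore").joinpath("data")
    with resources.as_file(base.joinpath("ips18.tsv")) as p:
        return load_signature(p)
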