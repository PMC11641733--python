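"""Containers and text formats for expression, clinical and signature data.

The package works on a genes x samples matrix of log-scale expression
intensities (e.g. RMA output) together with a per-sample clinical table
(RECIST response category, a continuous lesion-size response measure,
progression-free survival and covariates).  Everything downstream only
consumes within-sample orderings, so the absolute scale of the matrix is
irrelevant as long as it is comparable within a sample.

Formats are deliberately plain: tab-separated UTF-8 text, one header line,
no quoting.  The signature format is two gene columns plus a
``#threshold=<k>`` comment line carrying the vote threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD", "NA")
RESPONDER = "responder"
NON_RESPONDER = "non_responder"

CLINICAL_COLUMNS = [
    "sample_id",
    "response_category",
    "lesion_size",
    "pfs_time",
    "pfs_event",
    "age",
    "gender",
    "stage",
    "location",
]


class ExpressionMatrix:
    """Genes x samples real-valued expression matrix.

    Thin wrapper around a :class:`pandas.DataFrame` (index = gene ids,
    columns = sample ids) that enforces unique identifiers and finite
    values.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if data.columns.has_duplicates:
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        values = data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        self.data = data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        if "gene_id" not in df.columns:
            raise ValueError(f"{path}: expected first column 'gene_id'")
        df = df.set_index("gene_id")
        return cls(df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionMatrix) and self.data.equals(other.data)


class ClinicalTable:
    """Per-sample clinical annotations.

    Columns: RECIST response category (CR/PR/SD/PD/NA), continuous lesion
    size, PFS time (months) and event indicator, plus age/gender/stage/
    tumor-location covariates.  Missing entries are NA.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in CLINICAL_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        data = data.loc[:, CLINICAL_COLUMNS].copy()
        data["sample_id"] = data["sample_id"].astype(str)
        if data["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        cat = data["response_category"].fillna("NA")
        bad = sorted(set(cat) - set(RESPONSE_CATEGORIES))
        if bad:
            raise ValueError(f"unknown response categories: {bad}")
        data["response_category"] = cat
        ev = data["pfs_event"].dropna()
        if not ev.isin([0, 1]).all():
            raise ValueError("pfs_event must be 0 or 1")
        t = data["pfs_time"].dropna()
        if (t < 0).any():
            raise ValueError("pfs_time must be non-negative")
        self.data = data.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ClinicalTable":
        df = pd.read_csv(
            path, sep="\t", dtype={"sample_id": str},
            keep_default_na=True, na_values=[""],
        )
        # 'NA' in the categorical columns is a level, not missing
        for col in ("response_category", "location", "stage", "gender"):
            if col in df.columns:
                df[col] = df[col].where(df[col].notna(), "NA")
        return cls(df)


@dataclass
class ResponseLabels:
    """Binary responder labels derived from RECIST categories.

    ``labels`` maps sample_id -> {responder, non_responder}; samples that
    cannot be dichotomized (SD, NA) are listed in ``excluded_samples``.
    """

    labels: pd.Series
    excluded_samples: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def n_responders(self) -> int:
        return int((self.labels == RESPONDER).sum())

    @property
    def n_non_responders(self) -> int:
        return int((self.labels == NON_RESPONDER).sum())

    def as_bool(self, sample_ids: Iterable[str] | None = None) -> np.ndarray:
        """Boolean responder indicator, optionally in a given sample order."""
        s = self.labels if sample_ids is None else self.labels.loc[list(sample_ids)]
        return (s == RESPONDER).to_numpy()


def derive_labels(clinical: ClinicalTable) -> ResponseLabels:
    """Dichotomize RECIST categories into responder / non-responder.

    CR and PR count as response, PD as non-response; SD and NA samples are
    excluded from the labeled set.
    """
    cat = clinical.data.set_index("sample_id")["response_category"]
    responder = cat.isin(["CR", "PR"])
    non_responder = cat == "PD"
    excluded = cat.index[~(responder | non_responder)].tolist()
    labels = pd.Series(
        np.where(responder[responder | non_responder], RESPONDER, NON_RESPONDER),
        index=cat.index[responder | non_responder],
        name="label",
    )
    return ResponseLabels(labels=labels, excluded_samples=excluded)


def collapse_probes(
    probe_matrix: pd.DataFrame,
    probe_map: Mapping[str, Iterable[str]],
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    Probes mapping to no gene or to more than one gene are discarded;
    multiple probes for one gene are averaged (arithmetic mean per sample,
    on the provided log scale).  Genes left with any missing value are
    dropped — relative orderings are undefined on missing data.

    Parameters
    ----------
    probe_matrix : DataFrame, probes x samples, unique probe index.
    probe_map : mapping probe id -> iterable of gene ids.
    """
    if probe_matrix.index.has_duplicates:
        raise ValueError("probe ids must be unique")
    gene_of: dict[str, str] = {}
    for probe in probe_matrix.index:
        genes = list(probe_map.get(probe, ()))
        if len(genes) == 1:
            gene_of[probe] = str(genes[0])
    if not gene_of:
        raise ValueError(
            "no probes left after filtering: every probe maps to zero or multiple genes"
        )
    kept = probe_matrix.loc[list(gene_of)]
    collapsed = kept.groupby(pd.Series(gene_of), sort=True).mean()
    collapsed = collapsed.dropna(axis=0, how="any")
    if collapsed.empty:
        raise ValueError("no genes left after dropping genes with missing values")
    return ExpressionMatrix(collapsed.sort_index())


# ---------------------------------------------------------------------------
# signature / report serialization

def write_signature_tsv(path: str | Path, pairs: list[tuple[str, str]], threshold: int) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#threshold={threshold}\n")
        fh.write("gene_i\tgene_j\n")
        for gi, gj in pairs:
            fh.write(f"{gi}\t{gj}\n")


def read_signature_tsv(path: str | Path) -> tuple[list[tuple[str, str]], int]:
    threshold = None
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#threshold="):
                threshold = int(line.split("=", 1)[1])
            elif line.startswith("#") or line == "gene_i\tgene_j":
                continue
            else:
                gi, gj = line.split("\t")
                pairs.append((gi, gj))
    if threshold is None:
        raise ValueError(f"{path}: missing '#threshold=<k>' header line")
    return pairs, threshold


def write_report_json(path: str | Path, report: dict) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=_default)
        fh.write("\n")


def read_report_json(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
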