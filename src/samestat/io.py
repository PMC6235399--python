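"""Dataset I/O and validation.

All inputs are plain TSV with header rows: alternative-count and depth
matrices (mutations x samples, first column ``site_id``), a call matrix
with ``NA`` marking missing calls, an outcome table keyed by ``sample_id``,
and an optional site annotation mapping ``site_id`` (``chr:pos``, 1-based)
to a gene symbol. Validation enforces ``A <= D`` cellwise, consistent
sample ordering across tables, and the rule that a call is missing exactly
where depth falls below the calling threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gsame import GeneData
from .msame import CallErrorModel, SiteData
from .distributions import ReadCountModel

__all__ = [
    "Dataset",
    "read_dataset",
    "write_dataset",
    "bonferroni_threshold",
    "write_read_count_config",
    "read_read_count_config",
]

logger = logging.getLogger("samestat")


@dataclass
class Dataset:
    """Validated mutation read-count data plus outcomes and covariates."""

    A: pd.DataFrame  # mutations x samples
    D: pd.DataFrame
    O: pd.DataFrame  # NaN = missing call
    outcomes: pd.DataFrame  # index sample_id; column Y + covariates
    sites: pd.DataFrame  # index site_id; column gene
    d0: int = 20

    @property
    def sample_ids(self) -> list[str]:
        return list(self.outcomes.index)

    @property
    def site_ids(self) -> list[str]:
        return list(self.A.index)

    @property
    def Y(self) -> np.ndarray:
        return self.outcomes["Y"].to_numpy(dtype=float)

    @property
    def X(self) -> np.ndarray:
        cov = self.outcomes.drop(columns=["Y"])
        return cov.to_numpy(dtype=float)

    def site(self, site_id: str) -> SiteData:
        gene = ""
        if site_id in self.sites.index:
            gene = str(self.sites.loc[site_id, "gene"])
        return SiteData(
            self.A.loc[site_id].to_numpy(),
            self.D.loc[site_id].to_numpy(),
            self.O.loc[site_id].to_numpy(dtype=float),
            site_id=site_id,
            gene=gene,
        )

    def gene(self, gene_id: str) -> GeneData:
        ids = [s for s in self.site_ids
               if s in self.sites.index and self.sites.loc[s, "gene"] == gene_id]
        if not ids:
            raise KeyError(f"no sites annotated to gene {gene_id!r}")
        return GeneData(
            self.A.loc[ids].to_numpy(),
            self.D.loc[ids].to_numpy(),
            self.O.loc[ids].to_numpy(dtype=float),
            gene_id=gene_id,
            site_ids=ids,
        )

    def gene_ids(self) -> list[str]:
        return sorted(self.sites["gene"].dropna().unique().tolist())


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    return df


def read_dataset(
    alt_path,
    depth_path,
    calls_path,
    outcomes_path,
    sites_path=None,
    d0: int = 20,
) -> Dataset:
    """Load and cross-validate the four (five) input tables.

    Raises on sample-id mismatches (naming the offending ids), on any cell
    with more alternative than total reads (naming row and column), and on
    calls missing despite adequate depth. Calls made below the depth
    threshold are coerced to missing, with the coercion count logged.
    """
    A = _read_matrix(alt_path)
    D = _read_matrix(depth_path)
    O = _read_matrix(calls_path)
    outcomes = pd.read_csv(outcomes_path, sep="\t", index_col="sample_id")
    outcomes.index = outcomes.index.astype(str)
    if "Y" not in outcomes.columns:
        raise ValueError("outcome table must contain a 'Y' column")

    samples = list(outcomes.index)
    for name, df in (("alt", A), ("depth", D), ("calls", O)):
        extra = set(df.columns) - set(samples)
        missing = set(samples) - set(df.columns)
        if extra or missing:
            raise ValueError(
                f"sample ids in {name} matrix disagree with the outcome "
                f"table (extra: {sorted(extra)}, missing: {sorted(missing)})"
            )
    A, D, O = A[samples], D[samples], O[samples]
    if not (A.index.equals(D.index) and A.index.equals(O.index)):
        raise ValueError("site ids disagree across the count/call matrices")

    bad = A.to_numpy() > D.to_numpy()
    if bad.any():
        cells = [
            f"(site {A.index[i]}, sample {A.columns[j]})"
            for i, j in zip(*np.where(bad))
        ]
        raise ValueError("alt count exceeds depth at " + ", ".join(cells[:20]))

    Dv = D.to_numpy()
    Ov = O.to_numpy(dtype=float)
    low = Dv < d0
    coerced = int(np.sum(low & ~np.isnan(Ov)))
    if coerced:
        logger.warning("coerced %d calls at depth < d0=%d to missing", coerced, d0)
        Ov = np.where(low, np.nan, Ov)
        O = pd.DataFrame(Ov, index=O.index, columns=O.columns)
    bad_missing = ~low & np.isnan(Ov)
    if bad_missing.any():
        cells = [
            f"(site {O.index[i]}, sample {O.columns[j]})"
            for i, j in zip(*np.where(bad_missing))
        ]
        raise ValueError(
            "call missing despite adequate depth at " + ", ".join(cells[:20])
        )

    if sites_path is not None:
        sites = pd.read_csv(sites_path, sep="\t", index_col="site_id")
        sites.index = sites.index.astype(str)
    else:
        sites = pd.DataFrame({"gene": [""] * len(A.index)}, index=A.index)
    return Dataset(A=A, D=D, O=O, outcomes=outcomes, sites=sites, d0=d0)


def write_dataset(ds: Dataset, out_dir) -> dict[str, Path]:
    """Write the dataset back to TSV; inverse of :func:`read_dataset`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "alt": out / "counts_alt.tsv",
        "depth": out / "counts_depth.tsv",
        "calls": out / "calls.tsv",
        "outcomes": out / "outcomes.tsv",
        "sites": out / "sites.tsv",
    }
    ds.A.to_csv(paths["alt"], sep="\t", index_label="site_id")
    ds.D.to_csv(paths["depth"], sep="\t", index_label="site_id")
    ds.O.to_csv(paths["calls"], sep="\t", index_label="site_id", na_rep="NA")
    ds.outcomes.to_csv(paths["outcomes"], sep="\t", index_label="sample_id")
    ds.sites.to_csv(paths["sites"], sep="\t", index_label="site_id")
    return paths


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold under Bonferroni correction."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def write_read_count_config(rc: ReadCountModel, path) -> None:
    """Serialize the read-count components as flat ``key = value`` lines."""
    with open(path, "w") as fh:
        for key, val in rc.to_config().items():
            fh.write(f"{key} = {val!r}\n")


def read_read_count_config(path) -> ReadCountModel:
    cfg: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            cfg[key.strip()] = float(val)
    return ReadCountModel.from_config(cfg)
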