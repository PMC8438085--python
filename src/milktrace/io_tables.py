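"""Genus-level abundance tables: reading, validation, rarefaction, normalization, output.

Count tables hold one marker domain each (prokaryote 16S or fungal 18S); relative
abundance tables carry a (domain, genus) column MultiIndex so the two domains can
be concatenated while keeping per-domain compositional structure.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

COMPARTMENTS = ("soil", "phyllosphere", "cow-teat", "milk")
DOMAINS = ("prokaryote", "fungal")

#: canonical unordered compartment pairs, in chain order
COMPARTMENT_PAIRS = tuple(
    (COMPARTMENTS[i], COMPARTMENTS[j])
    for i in range(len(COMPARTMENTS))
    for j in range(i + 1, len(COMPARTMENTS))
)


class TableValidationError(ValueError):
    """A table violates a structural invariant (labels, signs, integrality)."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered compartment pair ``{a, b}`` in chain order."""
    if a not in COMPARTMENTS or b not in COMPARTMENTS:
        raise ValueError(f"unknown compartment in pair ({a!r}, {b!r})")
    if a == b:
        raise ValueError("a compartment pair needs two distinct compartments")
    return (a, b) if COMPARTMENTS.index(a) < COMPARTMENTS.index(b) else (b, a)


@dataclass
class GenusCountTable:
    """Integer read counts, samples x genera, for one marker domain.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with genus labels as columns.
    domain
        Marker-domain tag, one of ``("prokaryote", "fungal")``.
    """

    counts: pd.DataFrame
    domain: str

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise TableValidationError(f"unknown marker domain {self.domain!r}")
        df = self.counts
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate sample labels: {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate genus labels: {dup}")
        arr = df.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise TableValidationError("counts must be numeric")
            if np.any(arr < 0):
                raise TableValidationError("negative counts are not allowed")
            if not np.allclose(arr, np.round(arr)):
                raise TableValidationError("counts must be integral")
        self.counts = df.astype(np.int64)

    @property
    def samples(self) -> pd.Index:
        return self.counts.index

    @property
    def genera(self) -> pd.Index:
        return self.counts.columns

    @property
    def totals(self) -> pd.Series:
        """Per-sample read totals (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]


@dataclass
class RelAbundanceTable:
    """Per-sample genus proportions; columns are a (domain, genus) MultiIndex.

    Each marker domain is normalized independently: within a domain every row
    sums to the same constant (1 by default, so a merged prokaryote+fungal
    table has row sums of 2; 1/n_domains when a merged table was renormalized
    to an overall sum of 1).
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        cols = self.values.columns
        if not isinstance(cols, pd.MultiIndex) or cols.nlevels != 2:
            raise TableValidationError(
                "relative-abundance columns must be a (domain, genus) MultiIndex"
            )
        arr = self.values.to_numpy(dtype=float)
        if arr.size and (np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12)):
            raise TableValidationError("proportions must lie in [0, 1]")
        for dom in self.domains:
            rs = self.values[dom].sum(axis=1)
            if arr.size and not (
                np.allclose(rs, rs.iloc[0], atol=1e-9) and rs.iloc[0] <= 1 + 1e-9
            ):
                bad = rs.index[~np.isclose(rs, rs.iloc[0], atol=1e-9)].tolist()
                raise TableValidationError(
                    f"inconsistent per-domain row sums in domain {dom!r}: {bad}"
                )

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def domains(self) -> tuple[str, ...]:
        return tuple(self.values.columns.get_level_values(0).unique())


@dataclass
class SampleMetadata:
    """Maps each sample to (farm, compartment, marker domain).

    The same physical sample (one farm x compartment) may appear once per
    marker domain — the two sequencing runs share sample ids — so uniqueness
    is enforced on (sample, domain) and farm/compartment must agree across a
    sample's rows.
    """

    table: pd.DataFrame  # columns: sample, farm, compartment, domain

    REQUIRED = ("sample", "farm", "compartment", "domain")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise TableValidationError(f"metadata missing columns: {missing}")
        dup = self.table.duplicated(subset=["sample", "domain"])
        if dup.any():
            bad = self.table.loc[dup, "sample"].tolist()
            raise TableValidationError(
                f"duplicate metadata rows for (sample, domain): {bad}"
            )
        agree = self.table.groupby("sample")[["farm", "compartment"]].nunique()
        conflicted = agree.index[(agree > 1).any(axis=1)].tolist()
        if conflicted:
            raise TableValidationError(
                f"samples with conflicting farm/compartment: {conflicted}"
            )
        bad = set(self.table["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise TableValidationError(f"unknown compartments: {sorted(bad)}")
        bad = set(self.table["domain"]) - set(DOMAINS)
        if bad:
            raise TableValidationError(f"unknown marker domains: {sorted(bad)}")

    def for_samples(self, samples: Iterable[str]) -> pd.DataFrame:
        """Farm/compartment assignment for the given sample ids (one row each)."""
        idx = self.table.drop_duplicates(subset="sample").set_index("sample")
        samples = list(samples)
        missing = [s for s in samples if s not in idx.index]
        if missing:
            raise TableValidationError(f"samples without metadata: {missing}")
        return idx.loc[samples]

    @property
    def farms(self) -> list[str]:
        return sorted(self.table["farm"].unique())


# ---------------------------------------------------------------------------
# readers


def read_genus_table(path: str | os.PathLike, domain: str) -> GenusCountTable:
    """Read a genus count table from TSV (samples x genera) or BIOM-JSON.

    TSV layout: header row of genus labels, first column sample ids. BIOM-style
    input (``.biom``/``.json``) is parsed with the biom Table reader and
    transposed to samples-in-rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".biom", ".json"}:
        from skbio.table import Table

        with open(path) as fh:
            table = Table.from_json(json.load(fh))
        df = pd.DataFrame(
            table.matrix_data.toarray().T,
            index=list(table.ids("sample")),
            columns=list(table.ids("observation")),
        )
    else:
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except (pd.errors.ParserError, ValueError) as err:
            raise TableValidationError(f"cannot parse {path}: {err}") from err
        non_num = df.columns[
            [not np.issubdtype(dt, np.number) for dt in df.dtypes]
        ].tolist()
        if non_num:
            for col in non_num:
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
                if len(bad):
                    raise TableValidationError(
                        f"non-numeric count in {path} column {col!r}, row {bad[0]!r}"
                    )
            df = df.apply(pd.to_numeric)
    return GenusCountTable(df, domain=domain)


def read_metadata(path: str | os.PathLike) -> SampleMetadata:
    """Read sample metadata TSV with columns sample, farm, compartment, domain."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return SampleMetadata(pd.read_csv(path, sep="\t", dtype=str))


# ---------------------------------------------------------------------------
# normalization


def rarefy(
    table: GenusCountTable, depth: int = 10_000, seed: int | None = 0
) -> GenusCountTable:
    """Subsample each sample without replacement to ``depth`` reads.

    Samples whose total is at or below ``depth`` are kept whole (the study kept
    all reads for its two under-depth samples rather than dropping them).
    Subsampling is multivariate hypergeometric, i.e. random selection of reads
    without replacement, deterministic for a given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    out = table.counts.to_numpy().copy()
    totals = out.sum(axis=1)
    for i in np.flatnonzero(totals > depth):
        out[i] = rng.multivariate_hypergeometric(out[i], depth)
    return GenusCountTable(
        pd.DataFrame(out, index=table.samples, columns=table.genera),
        domain=table.domain,
    )


def to_relative_abundance(table: GenusCountTable) -> RelAbundanceTable:
    """Convert counts to per-sample proportions (each row sums to 1)."""
    totals = table.totals
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise TableValidationError(f"zero-total samples cannot be normalized: {zero}")
    values = table.counts.div(totals, axis=0)
    values.columns = pd.MultiIndex.from_product(
        [[table.domain], table.genera], names=["domain", "genus"]
    )
    return RelAbundanceTable(values)


def merge_domains(
    prok: RelAbundanceTable, fungal: RelAbundanceTable, renormalize: bool = False
) -> RelAbundanceTable:
    """Concatenate two single-domain tables column-wise over a shared sample set.

    By default per-domain normalization is preserved: a merged row sums to 2
    (1 per domain), keeping the within-domain compositional structure of the
    two independently normalized sequencing runs. With ``renormalize`` the
    merged rows are rescaled to an overall sum of 1 (a uniform rescale, since
    every merged row sums to exactly 2). Genus labels shared across domains
    stay distinct via the domain level of the column index.
    """
    sp, sf = set(prok.samples), set(fungal.samples)
    if sp != sf:
        raise TableValidationError(
            f"sample sets differ; only-first={sorted(sp - sf)} only-second={sorted(sf - sp)}"
        )
    merged = pd.concat([prok.values, fungal.values.loc[prok.samples]], axis=1)
    if renormalize:
        merged = merged / 2.0
    return RelAbundanceTable(merged)


# ---------------------------------------------------------------------------
# writers

_TSV_FLOAT = "%.12g"


def write_outputs(
    edges: pd.DataFrame | None,
    consensus: pd.DataFrame | None,
    reports: Sequence[Mapping] | None,
    out_dir: str | os.PathLike,
) -> dict[str, Path]:
    """Write per-farm edges (TSV), consensus edges (TSV + GraphML + JSON) and
    driver-model reports (JSON + markdown). Returns the written paths.

    Floats are serialized at 12 significant digits so a TSV round trip
    reproduces in-memory values.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if edges is not None:
        p = out / "farm_edges.tsv"
        edges.to_csv(p, sep="\t", index=False, float_format=_TSV_FLOAT)
        written["farm_edges"] = p
    if consensus is not None:
        p = out / "consensus_edges.tsv"
        consensus.to_csv(p, sep="\t", index=False, float_format=_TSV_FLOAT)
        written["consensus_edges"] = p
        written["consensus_graphml"] = _write_graphml(consensus, out / "consensus.graphml")
        pj = out / "consensus.json"
        pj.write_text(
            json.dumps(consensus.to_dict(orient="records"), indent=1, sort_keys=True)
        )
        written["consensus_json"] = pj
    if reports is not None:
        pj = out / "driver_models.json"
        pj.write_text(json.dumps(list(reports), indent=1, sort_keys=True))
        written["driver_models_json"] = pj
        pm = out / "driver_models.md"
        pm.write_text(_reports_markdown(reports))
        written["driver_models_md"] = pm
    return written


def _write_graphml(consensus: pd.DataFrame, path: Path) -> Path:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(COMPARTMENTS)
    for row in consensus.itertuples(index=False):
        g.add_edge(
            row.compartment_a,
            row.compartment_b,
            weight=float(row.consensus_weight),
            p_value=float(row.p_value),
            significant=bool(row.significant),
        )
    nx.write_graphml(g, path)
    return path


def _reports_markdown(reports: Sequence[Mapping]) -> str:
    lines = ["# Environmental drivers of inter-compartment link strength", ""]
    for rep in reports:
        lines.append(f"## {rep['link']}")
        lines.append(
            f"R2 = {rep['r_squared']:.3f}, R2_adj = {rep['r_squared_adj']:.3f}, "
            f"model P = {rep['model_p_value']:.4g}"
        )
        lines.append("")
        lines.append("| term | beta | beta_std | variance % |")
        lines.append("|---|---|---|---|")
        for term in rep["terms"]:
            lines.append(
                f"| {term['name']} | {term['coef']:.4g} | {term['coef_std']:.4g} "
                f"| {term['variance_pct']:.1f} |"
            )
        lines.append(f"| Residuals |  |  | {rep['residual_pct']:.1f} |")
        for opt in rep.get("optima", []):
            lines.append(
                f"- optimum of {opt['variable']}: {opt['x_star']:.4g}"
                + (" (interior maximum)" if opt["interior_maximum"] else "")
            )
        lines.append("")
    return "\n".join(lines)
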