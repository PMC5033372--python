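"""Gene panel, CT-table and reported-results I/O.

The data model is deliberately tidy/long: one row per well-level
measurement (animal x phase x group x brain region x gene), with an "ND"
sentinel for wells where the transcript never crossed threshold. Region,
phase and group vocabularies are closed sets; anything outside them is a
hard error at the boundary rather than silent missingness downstream.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
import numpy as np
import pandas as pd

REGIONS: tuple[str, ...] = (
    "cerebellum", "substantia nigra", "cortex", "pons", "hippocampus",
)
PHASES: tuple[str, ...] = ("discovery", "replication")
GROUPS: tuple[str, ...] = ("control", "PD")
ND_TOKEN = "ND"

CT_COLUMNS = ["animal_id", "phase", "group", "region", "gene", "ct"]

#: Coarse outcome labels used by the reported-results fixture and summaries.
COARSE_LABELS: tuple[str, ...] = (
    "significant_up", "significant_down", "trend_up", "trend_down",
    "no_change", "not_detected",
)

FIXTURE_COLUMNS = [
    "gene", "region", "discovery_percent", "replication_percent",
    "combined_percent", "discovery_p", "replication_p", "combined_p",
    "label", "note",
]


@dataclass(frozen=True)
class PanelEntry:
    gene: str
    protein: str
    family: str
    forward_primer: str
    reverse_primer: str


@dataclass(frozen=True)
class GenePanel:
    """The qPCR gene panel: 24 selenoprotein genes plus the dopaminergic
    marker (Th) and the housekeeping reference (Actb)."""

    entries: tuple[PanelEntry, ...]
    reference_gene: str = "Actb"
    marker_gene: str = "Th"

    def __post_init__(self) -> None:
        genes = [e.gene for e in self.entries]
        dupes = {g for g in genes if genes.count(g) > 1}
        if dupes:
            raise ValueError(f"duplicate gene symbols in panel: {sorted(dupes)}")
        for role, g in (("reference", self.reference_gene),
                        ("marker", self.marker_gene)):
            if g not in genes:
                raise ValueError(f"{role} gene {g!r} missing from panel")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(e.gene for e in self.entries)

    @property
    def target_genes(self) -> tuple[str, ...]:
        """Every assayed gene except the reference (marker included)."""
        return tuple(g for g in self.genes if g != self.reference_gene)

    @property
    def selenoprotein_genes(self) -> tuple[str, ...]:
        skip = {self.reference_gene, self.marker_gene}
        return tuple(g for g in self.genes if g not in skip)

    @property
    def selenoprotein_count(self) -> int:
        return len(self.selenoprotein_genes)

    def require_gene(self, gene: str) -> None:
        if gene not in self.genes:
            raise ValueError(f"gene {gene!r} not in panel")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("selenoqpcr.data") / name))


def load_panel(path: str | Path | None = None,
               reference_gene: str = "Actb",
               marker_gene: str = "Th") -> GenePanel:
    """Read the gene panel table (default: the packaged 26-gene panel)."""
    path = _data_path("panel.csv") if path is None else Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"gene", "protein", "forward_primer", "reverse_primer"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel file {path} lacks columns {sorted(missing)}")
    if "family" not in df.columns:
        df["family"] = ""
    entries = tuple(
        PanelEntry(r.gene, r.protein, r.family, r.forward_primer, r.reverse_primer)
        for r in df.itertuples()
    )
    return GenePanel(entries, reference_gene=reference_gene, marker_gene=marker_gene)


def default_panel() -> GenePanel:
    return load_panel()


def _fail_row(path, i: int, msg: str) -> ValueError:
    # +2: header line plus 1-based numbering
    return ValueError(f"{path}, data row {i + 1} (file line {i + 2}): {msg}")


def validate_ct_table(df: pd.DataFrame, panel: GenePanel,
                      path: str | Path = "<table>") -> pd.DataFrame:
    """Validate an in-memory CT frame against panel and vocabularies.

    Returns the frame with ``ct`` as float64 (NaN encodes not-detected).
    """
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[CT_COLUMNS].copy()
    vocab = {"phase": PHASES, "group": GROUPS, "region": REGIONS,
             "gene": panel.genes}
    for col, allowed in vocab.items():
        bad = ~df[col].isin(allowed)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise _fail_row(path, i, f"unknown {col} {df[col].iloc[i]!r}")
    ct_raw = df["ct"]
    if ct_raw.dtype == object or pd.api.types.is_string_dtype(ct_raw):
        s = ct_raw.astype(str).str.strip()
        is_nd = s == ND_TOKEN
        parsed = pd.to_numeric(s.mask(is_nd), errors="coerce")
        bad = parsed.isna() & ~is_nd
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise _fail_row(path, i, f"non-numeric CT {s.iloc[i]!r} (use {ND_TOKEN!r})")
        df["ct"] = parsed.astype(float)
    else:
        df["ct"] = ct_raw.astype(float)
    finite = df["ct"].dropna()
    if not np.isfinite(finite).all() or (finite < 0).any():
        bad = df["ct"].notna() & (~np.isfinite(df["ct"]) | (df["ct"] < 0))
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise _fail_row(path, i, f"CT must be finite and >= 0, got {df['ct'].iloc[i]}")
    df["animal_id"] = df["animal_id"].astype(str)
    return df.reset_index(drop=True)


def load_ct_table(path: str | Path, panel: GenePanel) -> pd.DataFrame:
    """Read a long-format CT table; "ND" marks not-detected wells."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if len(df) == 0:
        raise ValueError(f"{path}: CT table has no data rows")
    empty = (df.reindex(columns=CT_COLUMNS).fillna("") == "").any(axis=1)
    if empty.any():
        i = int(np.flatnonzero(empty.to_numpy())[0])
        raise _fail_row(path, i, "empty cell (not-detected must be spelled 'ND')")
    return validate_ct_table(df, panel, path)


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df[CT_COLUMNS].copy()
    out["ct"] = out["ct"].map(lambda v: ND_TOKEN if pd.isna(v) else repr(float(v)))
    out.to_csv(path, index=False)


_P_OPS = ("<", "=", ">")


def parse_p_annotation(text: str) -> tuple[str, float] | None:
    """Parse a printed p annotation such as "<0.05" or "=0.17".

    Returns (operator, value) or None for an empty annotation. Printed
    inequalities are kept as annotations because the underlying p is not
    recoverable from them.
    """
    s = str(text).strip()
    if not s or s.lower() in ("nan", "na"):
        return None
    op, body = (s[0], s[1:]) if s[0] in _P_OPS else ("=", s)
    try:
        v = float(body)
    except ValueError:
        raise ValueError(f"unparseable p annotation {text!r}") from None
    if not (0.0 <= v <= 1.0):
        raise ValueError(f"p annotation {text!r} outside [0, 1]")
    return op, v


def load_results_fixture(path: str | Path | None = None,
                         panel: GenePanel | None = None) -> pd.DataFrame:
    """Read the transcribed per-gene x region reported outcomes.

    Each row stores the printed percent changes (signed; decline negative),
    printed p annotations, and a coarse outcome label. Labels are checked
    against the sign of the stored percents at load time.
    """
    path = _data_path("reported_results.csv") if path is None else Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in FIXTURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[FIXTURE_COLUMNS].copy()
    for col in ("discovery_percent", "replication_percent", "combined_percent"):
        df[col] = pd.to_numeric(df[col].replace("", np.nan))
    for col in ("discovery_p", "replication_p", "combined_p"):
        df[col].map(parse_p_annotation)  # raises on malformed annotations
    bad_label = ~df["label"].isin(COARSE_LABELS)
    if bad_label.any():
        i = int(np.flatnonzero(bad_label.to_numpy())[0])
        raise _fail_row(path, i, f"unknown label {df['label'].iloc[i]!r}")
    if panel is not None:
        for col, allowed in (("gene", panel.genes), ("region", REGIONS)):
            bad = ~df[col].isin(allowed)
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise _fail_row(path, i, f"unknown {col} {df[col].iloc[i]!r}")
    pct_cols = ["discovery_percent", "replication_percent", "combined_percent"]
    for i, row in df.iterrows():
        pcts = [row[c] for c in pct_cols if pd.notna(row[c])]
        if row["label"] == "not_detected" and pcts:
            raise _fail_row(path, i, "not_detected entry carries a percent change")
        if row["label"].endswith("_up"):
            want = 1
        elif row["label"].endswith("_down"):
            want = -1
        else:
            want = None
        if want is not None and any(np.sign(p) != want for p in pcts):
            raise _fail_row(
                path, i,
                f"label {row['label']!r} inconsistent with percent sign(s) {pcts}")
    return df.reset_index(drop=True)


def load_abundance_fixture(path: str | Path | None = None,
                           panel: GenePanel | None = None) -> pd.DataFrame:
    """Read the transcribed control-mouse abundance bins (gene x region)."""
    from .relquant import ABUNDANCE_BINS  # local import avoids a cycle
    path = _data_path("abundance_bins.csv") if path is None else Path(path)
    df = pd.read_csv(path, dtype=str)
    for col in ("gene", "region", "bin"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    bad = ~df["bin"].isin(ABUNDANCE_BINS)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise _fail_row(path, i, f"unknown abundance bin {df['bin'].iloc[i]!r}")
    if panel is not None:
        unknown = set(df["gene"]) - set(panel.genes)
        if unknown:
            raise ValueError(f"{path}: genes not in panel: {sorted(unknown)}")
    return df.reset_index(drop=True)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as comma-separated UTF-8 text."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)

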