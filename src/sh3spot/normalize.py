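"""Raw SPOT intensities -> comparable per-domain binding profiles.

A SPOT experiment measures, for every peptide probe on a membrane, the
binding intensity of one tagged domain; each domain is assayed on its own
membrane in replicate.  Membranes differ in exposure/development, which
multiplies all intensities of a membrane by an arbitrary constant.  The
normalization is therefore carried out on the log2 scale:

1. ``log_transform``     — log2(intensity + pseudocount),
2. ``average_replicates`` — per-probe mean over a domain's replicates,
3. ``median_scale``      — shift every domain so all medians coincide.

Because an exposure change is an additive constant on the log2 scale and
the median is shift-equivariant, the default median scaling removes it
exactly: the pipeline output is invariant to multiplying any one domain's
raw intensities by a positive constant.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import validate_sequence

PEPTIDE_LENGTH = 15


@dataclass(frozen=True)
class PeptideProbe:
    """One 15-mer probe of the SPOT library."""

    probe_id: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))
        if len(self.sequence) != PEPTIDE_LENGTH:
            raise ValueError(
                f"probe {self.probe_id}: length {len(self.sequence)} != {PEPTIDE_LENGTH}"
            )


@dataclass
class PeptideLibrary:
    """The ordered set of probes carried by a membrane.

    Wraps a ``pd.Series`` probe_id -> sequence; this index set labels every
    binding profile downstream.
    """

    sequences: pd.Series

    def __post_init__(self):
        seqs = pd.Series(self.sequences, dtype=str)
        if seqs.index.has_duplicates:
            raise ValueError("duplicate probe ids in library")
        for pid, s in seqs.items():
            PeptideProbe(str(pid), s)
        self.sequences = seqs.astype(str).str.upper()

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def probe_ids(self) -> pd.Index:
        return self.sequences.index

    # -- I/O ----------------------------------------------------------------
    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write("probe_id\tsequence\n")
            for pid, s in self.sequences.items():
                fh.write(f"{pid}\t{s}\n")

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(s), id=str(pid), description="")
            for pid, s in self.sequences.items()
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_tsv(cls, path) -> "PeptideLibrary":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        return cls(pd.Series(df["sequence"].values, index=df["probe_id"].values))

    @classmethod
    def from_fasta(cls, path) -> "PeptideLibrary":
        recs = list(SeqIO.parse(path, "fasta"))
        return cls(pd.Series({r.id: str(r.seq) for r in recs}))


@dataclass
class SpotExperiment:
    """Raw or log-scale intensities for (domain, replicate) over the library.

    ``intensities`` is probes x (domain, replicate), a DataFrame whose
    columns are a 2-level MultiIndex.
    """

    probes: PeptideLibrary
    intensities: pd.DataFrame
    scale: str = "raw"  # "raw" | "log2"

    def __post_init__(self):
        df = self.intensities
        if not isinstance(df.columns, pd.MultiIndex) or df.columns.nlevels != 2:
            raise ValueError("intensities need (domain, replicate) column MultiIndex")
        if not df.index.equals(self.probes.probe_ids):
            raise ValueError("intensity rows must cover the full probe library")
        if self.scale == "raw" and (df.values < 0).any():
            raise ValueError("negative raw intensities")

    @property
    def domains(self) -> list[str]:
        return list(dict.fromkeys(self.intensities.columns.get_level_values(0)))

    # -- I/O ----------------------------------------------------------------
    def to_long_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write("domain\treplicate\tprobe_id\tintensity\n")
            for (dom, rep) in self.intensities.columns:
                col = self.intensities[(dom, rep)]
                for pid, v in col.items():
                    fh.write(f"{dom}\t{rep}\t{pid}\t{v:.6f}\n")

    @classmethod
    def from_long_tsv(cls, path, probes: PeptideLibrary) -> "SpotExperiment":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"probe_id": str})
        wide = df.pivot_table(
            index="probe_id", columns=["domain", "replicate"], values="intensity"
        )
        if wide.isna().any().any():
            raise ValueError("missing probe/replicate combinations in intensity table")
        wide = wide.loc[probes.probe_ids]
        return cls(probes, wide)


@dataclass
class BindingProfile:
    """Normalized log2 binding profile of one domain over the library."""

    domain_id: str
    values: pd.Series
    n_replicates: int = 1

    def __post_init__(self):
        if not np.isfinite(self.values.values).all():
            raise ValueError(f"non-finite values in profile {self.domain_id}")


@dataclass
class ProfilePanel:
    """All domains' normalized profiles over one shared probe index.

    ``values`` is probes x domains; ``metadata`` (indexed by domain id)
    carries ``family`` and ``species`` columns.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame = None
    n_replicates: pd.Series = None
    global_median: float = field(default=np.nan)

    def __post_init__(self):
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate domain ids in panel")
        if self.metadata is None:
            self.metadata = pd.DataFrame(
                index=self.values.columns, columns=["family", "species"]
            )
        if self.n_replicates is None:
            self.n_replicates = pd.Series(1, index=self.values.columns)

    @property
    def domains(self) -> list[str]:
        return list(self.values.columns)

    def profile(self, domain_id: str) -> BindingProfile:
        return BindingProfile(
            domain_id,
            self.values[domain_id],
            int(self.n_replicates.get(domain_id, 1)),
        )

    def subset(self, domains) -> "ProfilePanel":
        domains = list(domains)
        return ProfilePanel(
            self.values[domains],
            self.metadata.loc[domains],
            self.n_replicates[domains],
            self.global_median,
        )

    # -- I/O ----------------------------------------------------------------
    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.values.to_csv(fh, sep="\t", index_label="probe_id")
        side = str(path) + ".meta.json"
        with open(side, "w") as fh:
            json.dump(
                {
                    "metadata": self.metadata.to_dict(orient="index"),
                    "n_replicates": {k: int(v) for k, v in self.n_replicates.items()},
                    "global_median": None
                    if np.isnan(self.global_median)
                    else float(self.global_median),
                },
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_tsv(cls, path) -> "ProfilePanel":
        values = pd.read_csv(path, sep="\t", comment="#", index_col="probe_id")
        values.index = values.index.astype(str)
        meta = None
        n_rep = None
        gmed = np.nan
        try:
            with open(str(path) + ".meta.json") as fh:
                side = json.load(fh)
            meta = pd.DataFrame.from_dict(side.get("metadata", {}), orient="index")
            n_rep = pd.Series(side.get("n_replicates", {}))
            if side.get("global_median") is not None:
                gmed = float(side["global_median"])
        except FileNotFoundError:
            pass
        return cls(values, meta, n_rep, gmed)


# ---------------------------------------------------------------------------
# operations


def log_transform(x: SpotExperiment, pseudocount: float = 1.0) -> SpotExperiment:
    """Replace every intensity v by log2(v + pseudocount)."""
    vals = x.intensities.values
    if (vals < 0).any():
        raise ValueError("negative intensities cannot be log-transformed")
    if pseudocount <= 0 and (vals <= 0).any():
        raise ValueError("pseudocount must be > 0 unless all intensities are > 0")
    out = np.log2(x.intensities + pseudocount)
    return SpotExperiment(x.probes, out, scale="log2")


def average_replicates(x: SpotExperiment) -> tuple[pd.DataFrame, pd.Series]:
    """Per-probe mean over each domain's replicates (on the log2 scale).

    Returns ``(profiles, n_replicates)`` with profiles probes x domains.
    """
    if x.scale != "log2":
        warnings.warn("averaging replicates on a non-log2 scale", stacklevel=2)
    profiles = x.intensities.T.groupby(level=0).mean().T
    n_rep = x.intensities.T.groupby(level=0).size()
    return profiles[sorted(profiles.columns)], n_rep.sort_index()


def median_scale(
    profiles: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    n_replicates: pd.Series | None = None,
    target: float | str = "common",
) -> ProfilePanel:
    """Shift each domain's log2 profile so every domain median coincides.

    ``target="common"`` (default) centers each domain on its own median and
    adds back the median of the pooled *centered* values; because centered
    values are untouched by any per-domain shift, the result is exactly
    invariant to a membrane exposure change (a per-domain multiplicative
    factor on the raw scale).  ``target="pooled"`` instead shifts every
    domain by (median of pooled input values − domain median), the textbook
    batch median-scaling; it equalizes medians identically but the common
    level then tracks the pooled input.  A float target fixes the common
    median explicitly.  Correlations between domains are identical under
    every choice.
    """
    if profiles.shape[1] < 1 or profiles.shape[0] < 1:
        raise ValueError("median_scale needs at least one domain and one probe")
    if profiles.isna().any().any():
        raise ValueError("NA values in profiles")
    med = profiles.median(axis=0)
    centered = profiles - med
    if target == "common":
        gmed = float(np.median(centered.values))
    elif target == "pooled":
        gmed = float(np.median(profiles.values))
    else:
        gmed = float(target)
    out = centered + gmed
    return ProfilePanel(out, metadata, n_replicates, global_median=gmed)


def normalize_experiment(
    x: SpotExperiment,
    metadata: pd.DataFrame | None = None,
    pseudocount: float = 1.0,
    target: float | str = "common",
) -> ProfilePanel:
    """Full pipeline: log2 transform, replicate average, median scaling."""
    logged = log_transform(x, pseudocount)
    profiles, n_rep = average_replicates(logged)
    return median_scale(profiles, metadata, n_rep, target=target)
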