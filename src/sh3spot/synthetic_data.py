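"""Synthetic SPOT studies with known ground truth.

Generates the four inputs the analysis consumes — a 15-mer peptide
library, raw SPOT intensities for a panel of domains, domain sequences
for families diverged at controlled rates, and proteomes with planted
binding sites — all as pure functions of a :class:`GeneratorConfig`
(identical config, identical bytes).

The intensity model is log-normal: the log2 intensity of domain *d* on
peptide *p*, replicate *r* is

    mu + offset_d + gain * 1[class(d) == class(p)] + eta_{d,p} + eps_{d,p,r}

with a per-membrane offset ``offset_d ~ N(0, membrane_offset_sd)``,
replicate noise ``eps ~ N(0, replicate_noise_sd)`` and a per-domain
profile drift ``eta_{d,p} ~ N(0, profile_drift_sd * sqrt(rate_f(d)))``
shared across replicates.  The drift term ties profile divergence to the
same per-family rate that mutates the domain sequences, so sequence
identity and profile correlation decay together within a family — the
coupling the conservation analysis measures.  With drift, offsets and
noise at 0 the model degenerates to constant intensities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .alphabet import AA20
from .conservation import DomainRecord
from .motifs import (
    CLASSES,
    HYDROPHOBIC,
    PWM,
    PWM_WIDTH,
    classify_motif,
    consensus_pwm,
    sample_from_pwm,
)
from .normalize import PeptideLibrary, SpotExperiment

#: peptide background: uniform over the 19 non-cysteine residues
#: (membrane-synthesized probes replace every cysteine by serine).
PEPTIDE_ALPHABET = AA20.replace("C", "")

#: proteome background: uniform over all 20 residues.
PROTEIN_ALPHABET = AA20


@dataclass
class ProteomeConfig:
    n_proteins: int = 100
    mean_length: int = 200
    n_planted_sites: int = 20
    planted_class: str = "III"
    planted_strength: float = 0.95


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic SPOT experiment."""

    seed: int = 0
    n_peptides: int = 292
    n_families: int = 6
    species_labels: tuple = ("Ag", "Ca", "Sc", "Sp")
    class_mix: dict = field(
        default_factory=lambda: {"I": 0.3, "II": 0.3, "I*": 0.1, "III": 0.3}
    )
    affinity_gain: float = 4.0  # log2-units added on a class match
    replicate_noise_sd: float = 0.5  # log2-units
    membrane_offset_sd: float = 0.5  # log2-units
    n_replicates: int = 2
    baseline_log2: float = 10.0  # arbitrary scale; removed by normalization
    domain_classes: tuple = ("II", "I", "III")  # cycled over families
    ancestor_length: int = 60
    profile_divergence: float | Sequence[float] = 0.15  # per-site mutation rate
    divergence_spread: float = 4.0  # geometric spread of rates across families
    profile_drift_sd: float = 1.5  # log2-units per sqrt(unit rate)
    proteome: ProteomeConfig = field(default_factory=ProteomeConfig)

    def __post_init__(self):
        if isinstance(self.proteome, dict):
            self.proteome = ProteomeConfig(**self.proteome)
        self.validate()

    def validate(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1, got {total}")
        bad = set(self.class_mix) - set(CLASSES) - {"none"}
        if bad:
            raise ValueError(f"unknown classes in class_mix: {sorted(bad)}")
        if any(v < 0 for v in self.class_mix.values()):
            raise ValueError("class_mix proportions must be non-negative")
        for name in ("replicate_noise_sd", "membrane_offset_sd", "profile_drift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_peptides < 20:
            raise ValueError("n_peptides must be >= 20")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per domain")

    # -- derived layout -----------------------------------------------------
    @property
    def families(self) -> list[str]:
        return [f"fam{i:02d}" for i in range(self.n_families)]

    @property
    def domain_ids(self) -> list[str]:
        return [f"{f}-{s}" for f in self.families for s in self.species_labels]

    def family_rates(self) -> dict[str, float]:
        """Per-family sequence/profile divergence rates.

        A scalar ``profile_divergence`` is spread geometrically over
        families by ``divergence_spread`` (factor 1/spread .. spread), so a
        default panel contains both tightly and loosely conserved families;
        a sequence gives explicit per-family rates.
        """
        if isinstance(self.profile_divergence, (int, float)):
            if self.n_families == 1 or self.divergence_spread <= 1:
                rates = [float(self.profile_divergence)] * self.n_families
            else:
                rates = list(
                    float(self.profile_divergence)
                    * np.geomspace(
                        1.0 / self.divergence_spread,
                        self.divergence_spread,
                        self.n_families,
                    )
                )
        else:
            rates = [float(x) for x in self.profile_divergence]
            if len(rates) != self.n_families:
                raise ValueError("profile_divergence list length != n_families")
        return dict(zip(self.families, rates))


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators.

    Coordinates in ``planted_sites`` are 0-based half-open
    ``(protein_id, start, motif_class)`` with the site occupying
    ``protein[start:start+15]``.
    """

    peptide_class: dict = field(default_factory=dict)
    domain_class: dict = field(default_factory=dict)
    domain_family: dict = field(default_factory=dict)
    domain_species: dict = field(default_factory=dict)
    planted_sites: list = field(default_factory=list)
    planted_identity: dict = field(default_factory=dict)  # "a|b" -> fraction

    def metadata_frame(self) -> pd.DataFrame:
        """Domain metadata as the panel expects it (family, species)."""
        return pd.DataFrame(
            {
                "family": pd.Series(self.domain_family),
                "species": pd.Series(self.domain_species),
            }
        )

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["planted_sites"] = [list(t) for t in self.planted_sites]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["planted_sites"] = [tuple(t) for t in payload.get("planted_sites", [])]
        return cls(**payload)


def _init_domains(truth: SyntheticTruth, cfg: GeneratorConfig) -> None:
    """Fill the domain layout (family, species, class) if not already set."""
    if truth.domain_class:
        return
    for fi, fam in enumerate(cfg.families):
        cls = cfg.domain_classes[fi % len(cfg.domain_classes)]
        for sp in cfg.species_labels:
            did = f"{fam}-{sp}"
            truth.domain_class[did] = cls
            truth.domain_family[did] = fam
            truth.domain_species[did] = sp


# ---------------------------------------------------------------------------
# peptide library


def _random_background(rng, length, alphabet=PEPTIDE_ALPHABET) -> list[str]:
    return [alphabet[i] for i in rng.integers(0, len(alphabet), length)]


def _motif_instance(rng, cls: str) -> str:
    bg = PEPTIDE_ALPHABET
    bg_nock = "".join(a for a in bg if a not in "RK")
    x = lambda: bg[rng.integers(len(bg))]  # noqa: E731
    xn = lambda: bg_nock[rng.integers(len(bg_nock))]  # noqa: E731
    charge = "RK"[rng.integers(2)]
    if cls == "I":
        return charge + x() + x() + "P" + x() + x() + "P"
    if cls == "II":
        return "P" + x() + x() + "P" + x() + charge
    if cls == "I*":
        phi = HYDROPHOBIC[rng.integers(len(HYDROPHOBIC))]
        return charge + x() + x() + phi + x() + x() + "P"
    if cls == "III":
        # polyproline: PxxPxxP scaffold whose x positions are themselves
        # proline half the time, giving the proline-rich runs typical of
        # this class
        mid = ["P" if rng.random() < 0.5 else xn() for _ in range(4)]
        return "P" + mid[0] + mid[1] + "P" + mid[2] + mid[3] + "P"
    raise ValueError(f"unknown class {cls!r}")


def _apportion(mix: dict, n: int) -> dict:
    """Largest-remainder apportionment of n peptides over classes."""
    keys = sorted(mix)
    exact = {k: mix[k] * n for k in keys}
    counts = {k: int(np.floor(exact[k])) for k in keys}
    short = n - sum(counts.values())
    remainders = sorted(keys, key=lambda k: (-(exact[k] - counts[k]), k))
    for k in remainders[:short]:
        counts[k] += 1
    return counts


def generate_library(
    cfg: GeneratorConfig, truth: SyntheticTruth | None = None
) -> tuple[PeptideLibrary, SyntheticTruth]:
    """A cysteine-free 15-mer library with a controlled motif-class mix.

    Each peptide embeds a single class instance at a uniformly random
    admissible offset within background sequence (uniform over the 19
    non-Cys residues) and is rejection-sampled until the classifier
    assigns exactly the intended class, so the recorded truth is exact.
    """
    cfg.validate()
    truth = truth if truth is not None else SyntheticTruth()
    rng = np.random.default_rng([cfg.seed, 11])

    counts = _apportion(cfg.class_mix, cfg.n_peptides)
    classes = [k for k in sorted(counts) for _ in range(counts[k])]
    rng.shuffle(classes)

    seqs = {}
    for i, cls in enumerate(classes):
        pid = f"p{i + 1:04d}"
        for _attempt in range(1000):
            chars = _random_background(rng, PWM_WIDTH)
            if cls != "none":
                core = _motif_instance(rng, cls)
                off = int(rng.integers(0, PWM_WIDTH - len(core) + 1))
                chars[off : off + len(core)] = list(core)
            seq = "".join(chars)
            if classify_motif(seq) == cls:
                break
        else:
            raise RuntimeError(f"could not generate a clean class-{cls} peptide")
        seqs[pid] = seq
        truth.peptide_class[pid] = cls
    return PeptideLibrary(pd.Series(seqs)), truth


# ---------------------------------------------------------------------------
# SPOT intensities


def generate_spot_experiment(
    lib: PeptideLibrary, truth: SyntheticTruth, cfg: GeneratorConfig
) -> SpotExperiment:
    """Raw intensities 2^(mu + offset_d + gain*match + eta_dp + eps_dpr)."""
    cfg.validate()
    if len(lib) == 0:
        raise ValueError("empty peptide library")
    _init_domains(truth, cfg)
    rng = np.random.default_rng([cfg.seed, 12])
    rates = cfg.family_rates()

    pep_classes = np.array([truth.peptide_class.get(p, "none") for p in lib.probe_ids])
    columns = []
    data = []
    for did in cfg.domain_ids:
        offset = rng.normal(0.0, cfg.membrane_offset_sd)
        match = (pep_classes == truth.domain_class[did]).astype(float)
        drift_sd = cfg.profile_drift_sd * np.sqrt(rates[truth.domain_family[did]])
        eta = rng.normal(0.0, drift_sd, size=len(lib)) if drift_sd > 0 else 0.0
        base = cfg.baseline_log2 + offset + cfg.affinity_gain * match + eta
        for r in range(cfg.n_replicates):
            eps = (
                rng.normal(0.0, cfg.replicate_noise_sd, size=len(lib))
                if cfg.replicate_noise_sd > 0
                else 0.0
            )
            columns.append((did, f"r{r + 1}"))
            data.append(np.exp2(base + eps))
    intensities = pd.DataFrame(
        np.column_stack(data),
        index=lib.probe_ids,
        columns=pd.MultiIndex.from_tuples(columns, names=["domain", "replicate"]),
    )
    return SpotExperiment(lib, intensities, scale="raw")


# ---------------------------------------------------------------------------
# domain sequences


def generate_domain_sequences(
    truth: SyntheticTruth, cfg: GeneratorConfig
) -> list[DomainRecord]:
    """Family members derived from one ancestor per family.

    Each member carries a Poisson(rate_f * length) number of point
    substitutions (positions drawn with replacement, new residue uniform
    over all 20, so high rates relax to the ~5% background identity of a
    uniform composition).  Realized within-family pairwise identities are
    recorded in ``truth.planted_identity``.
    """
    cfg.validate()
    _init_domains(truth, cfg)
    rng = np.random.default_rng([cfg.seed, 13])
    rates = cfg.family_rates()
    L = cfg.ancestor_length

    records = []
    for fam in cfg.families:
        ancestor = np.array(
            [PROTEIN_ALPHABET[i] for i in rng.integers(0, 20, L)], dtype="<U1"
        )
        members = {}
        for sp in cfg.species_labels:
            seq = ancestor.copy()
            k = rng.poisson(rates[fam] * L)
            for pos in rng.integers(0, L, k):
                seq[pos] = PROTEIN_ALPHABET[rng.integers(20)]
            members[f"{fam}-{sp}"] = seq
        ids = sorted(members)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                ident = float(np.mean(members[a] == members[b]))
                truth.planted_identity[f"{a}|{b}"] = ident
        for did in ids:
            records.append(
                DomainRecord(
                    did,
                    truth.domain_species[did],
                    truth.domain_family[did],
                    "".join(members[did]),
                )
            )
    return records


# ---------------------------------------------------------------------------
# proteome


def generate_proteome(
    truth: SyntheticTruth,
    cfg: GeneratorConfig,
    pwm: PWM | None = None,
) -> dict[str, str]:
    """Background proteins with planted 15-residue PWM sites.

    Proteins are drawn from a uniform 20-residue composition with
    Poisson-distributed lengths; each planted site replaces one window
    with a sample from ``pwm`` (default: the high-information consensus
    PWM of ``cfg.proteome.planted_class``).  Sites never overlap; their
    0-based half-open coordinates go to ``truth.planted_sites``.
    """
    cfg.validate()
    pc = cfg.proteome
    rng = np.random.default_rng([cfg.seed, 14])
    proteins: dict[str, np.ndarray] = {}
    for i in range(pc.n_proteins):
        length = max(PWM_WIDTH, int(rng.poisson(pc.mean_length)))
        proteins[f"prot{i + 1:04d}"] = np.array(
            [PROTEIN_ALPHABET[j] for j in rng.integers(0, 20, length)], dtype="<U1"
        )

    n_windows = sum(len(s) - PWM_WIDTH + 1 for s in proteins.values())
    if pc.n_planted_sites > n_windows:
        raise ValueError("more planted sites requested than available windows")

    if pwm is None and pc.n_planted_sites > 0:
        pwm = consensus_pwm(pc.planted_class, pc.planted_strength)
    ids = sorted(proteins)
    occupied: dict[str, list[tuple[int, int]]] = {pid: [] for pid in ids}
    planted = 0
    attempts = 0
    while planted < pc.n_planted_sites:
        attempts += 1
        if attempts > 1000 * pc.n_planted_sites:
            raise RuntimeError("could not place non-overlapping planted sites")
        pid = ids[rng.integers(len(ids))]
        seq = proteins[pid]
        if len(seq) < PWM_WIDTH:
            continue
        start = int(rng.integers(0, len(seq) - PWM_WIDTH + 1))
        if any(start < e and s < start + PWM_WIDTH for s, e in occupied[pid]):
            continue
        site = sample_from_pwm(pwm, 1, rng)[0]
        seq[start : start + PWM_WIDTH] = list(site)
        occupied[pid].append((start, start + PWM_WIDTH))
        truth.planted_sites.append((pid, start, pc.planted_class))
        planted += 1
    return {pid: "".join(proteins[pid]) for pid in ids}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for pid in seqs:
            fh.write(f">{pid}\n")
            s = seqs[pid]
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# scenarios


def apply_class_switch(
    truth: SyntheticTruth, domain_id: str, new_class: str
) -> SyntheticTruth:
    """Switch one domain's binding class while leaving its sequence alone.

    Emulates a paralog whose specificity diverged without matching sequence
    divergence: after regenerating the SPOT experiment the domain's profile
    belongs to ``new_class`` although its sequence identity to its family
    stays high.
    """
    if domain_id not in truth.domain_class:
        raise KeyError(f"unknown domain {domain_id}")
    if new_class not in CLASSES:
        raise ValueError(f"unknown class {new_class!r}")
    truth.domain_class[domain_id] = new_class
    return truth


def class_switch_scenario(
    cfg: GeneratorConfig,
) -> tuple[PeptideLibrary, SyntheticTruth, list[DomainRecord], SpotExperiment, str]:
    """A conserved panel with one high-identity, class-switched paralog.

    Picks the member of the *lowest-divergence* family whose species label
    sorts last, rewrites its sequence as a near-copy (one substitution) of
    a family sibling so its identity is the highest in the family, and
    flips its binding class to a class not used by its family, before
    simulating the SPOT experiment.  Returns
    ``(library, truth, domain_records, experiment, switched_domain_id)``.
    """
    lib, truth = generate_library(cfg)
    _init_domains(truth, cfg)
    records = generate_domain_sequences(truth, cfg)
    rates = cfg.family_rates()
    fam = min(cfg.families, key=lambda f: (rates[f], f))
    switched = f"{fam}-{sorted(cfg.species_labels)[-1]}"

    # high-identity sequence: sibling copy with a single substitution
    siblings = sorted(
        r.domain_id for r in records
        if r.family == fam and r.domain_id != switched
    )
    partner = next(r for r in records if r.domain_id == siblings[0])
    chars = list(partner.sequence)
    chars[0] = next(a for a in PROTEIN_ALPHABET if a != chars[0])
    new_seq = "".join(chars)
    by_id = {r.domain_id: r for r in records}
    by_id[switched] = DomainRecord(
        switched, truth.domain_species[switched], fam, new_seq
    )
    records = [by_id[r.domain_id] for r in records]
    for other in siblings:
        a, b = sorted((switched, other))
        truth.planted_identity[f"{a}|{b}"] = float(
            np.mean(
                np.frombuffer(new_seq.encode(), dtype="S1")
                == np.frombuffer(by_id[other].sequence.encode(), dtype="S1")
            )
        )

    old = truth.domain_class[switched]
    new = next(c for c in ("I", "II", "III") if c != old)
    apply_class_switch(truth, switched, new)
    expt = generate_spot_experiment(lib, truth, cfg)
    return lib, truth, records, expt, switched
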