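"""Synthetic vaginal-community cohorts with known sub-CST structure.

The generator emulates the structure of real 16S rRNA cohorts of
reproductive-age women: most samples dominated by a single *Lactobacillus*
species (CSTs I, II, III, V) or by *Gardnerella vaginalis* /
*Ca. Lachnocurva vaginae* (CSTs IV-A, IV-B), and a minority of diverse,
even anaerobic communities (CST IV-C and its five subtypes). Each sample
is produced by:

1. drawing a sub-CST from the mixture weights (prevalences),
2. drawing a composition from a Dirichlet centred on that sub-CST's
   target profile, with a per-sub-CST concentration controlling the
   within-type spread,
3. drawing a sequencing depth log-uniformly over the configured range, and
4. drawing taxon read counts from a multinomial at that depth.

Everything is reproducible under a fixed seed; per-stage substreams are
derived from the master seed so adding a stage does not perturb earlier
draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import phylotypes as pt
from .errors import ValidationError
from .metrics import NUGENT_CATEGORIES, PH_CATEGORIES
from .taxa_io import CountTable

#: Minor-taxon tail over which each profile's remainder mass is spread, so
#: rare-taxon filtering and union-vocabulary handling get exercised.
MINOR_TAXA = (
    "Sneathia_amnii",
    "Mobiluncus_curtisii",
    "Prevotella_timonensis",
    "g_Megasphaera",
    "g_Dialister",
    "g_Anaerococcus",
    "g_Peptoniphilus",
    "g_Finegoldia",
    "g_Aerococcus",
    "g_Parvimonas",
    "g_Gemella",
    "g_Corynebacterium",
    "g_Veillonella",
    "g_Fusobacterium",
    "g_Porphyromonas",
    "g_Ureaplasma",
    "g_Mycoplasma",
    "g_Clostridium",
    "g_Actinomyces",
    "g_Peptostreptococcus",
)

# Qualitative dominance structure of the 13 sub-CSTs over the 12 key taxa;
# the unassigned remainder of each profile is spread over MINOR_TAXA with a
# geometric decay. CST V carries 0.20 L. iners alongside L. jensenii (the
# two species co-occur).
_PROFILE_CORES: dict[str, dict[str, float]] = {
    "I-A": {pt.L_CRISPATUS: 0.90, pt.L_INERS: 0.02, pt.G_VAGINALIS: 0.01},
    "I-B": {
        pt.L_CRISPATUS: 0.55,
        pt.L_INERS: 0.15,
        pt.G_VAGINALIS: 0.05,
        pt.A_VAGINAE: 0.02,
        pt.PREVOTELLA: 0.03,
    },
    "II": {pt.L_GASSERI: 0.80, pt.L_INERS: 0.05, pt.G_VAGINALIS: 0.03},
    "III-A": {pt.L_INERS: 0.90, pt.L_CRISPATUS: 0.02},
    "III-B": {
        pt.L_INERS: 0.55,
        pt.G_VAGINALIS: 0.15,
        pt.A_VAGINAE: 0.05,
        pt.PREVOTELLA: 0.05,
    },
    "IV-A": {
        pt.CA_L_VAGINAE: 0.45,
        pt.G_VAGINALIS: 0.20,
        pt.A_VAGINAE: 0.10,
        pt.PREVOTELLA: 0.08,
        pt.L_INERS: 0.05,
    },
    "IV-B": {
        pt.G_VAGINALIS: 0.55,
        pt.A_VAGINAE: 0.15,
        pt.PREVOTELLA: 0.05,
        pt.L_INERS: 0.08,
        pt.CA_L_VAGINAE: 0.02,
    },
    "IV-C0": {
        pt.PREVOTELLA: 0.20,
        pt.STREPTOCOCCUS: 0.08,
        pt.G_VAGINALIS: 0.05,
        pt.A_VAGINAE: 0.05,
        pt.ENTEROCOCCUS: 0.05,
        pt.BIFIDOBACTERIUM: 0.05,
        pt.STAPHYLOCOCCUS: 0.05,
        pt.L_INERS: 0.05,
        pt.CA_L_VAGINAE: 0.02,
    },
    "IV-C1": {pt.STREPTOCOCCUS: 0.70, pt.PREVOTELLA: 0.05, pt.L_INERS: 0.05},
    "IV-C2": {pt.ENTEROCOCCUS: 0.70, pt.PREVOTELLA: 0.05, pt.L_INERS: 0.03},
    "IV-C3": {pt.BIFIDOBACTERIUM: 0.75, pt.L_INERS: 0.05},
    "IV-C4": {pt.STAPHYLOCOCCUS: 0.70, pt.PREVOTELLA: 0.05, pt.L_INERS: 0.03},
    "V": {pt.L_JENSENII: 0.65, pt.L_INERS: 0.20, pt.L_CRISPATUS: 0.03},
}

#: Sub-CST prevalences: Lactobacillus-dominated types are the majority,
#: IV-C as a whole is rare (~6% of samples).
_DEFAULT_WEIGHTS = {
    "I-A": 0.16,
    "I-B": 0.08,
    "II": 0.03,
    "III-A": 0.22,
    "III-B": 0.16,
    "IV-A": 0.09,
    "IV-B": 0.17,
    "IV-C0": 0.020,
    "IV-C1": 0.015,
    "IV-C2": 0.007,
    "IV-C3": 0.012,
    "IV-C4": 0.006,
    "V": 0.03,
}

#: Sequencing-depth range (reads per sample), drawn log-uniformly.
DEFAULT_DEPTH_RANGE = (1005, 411805)

#: Moderate within-type spread; produces a grey zone between related types
#: (e.g. III vs V) like real cohorts show.
DEFAULT_CONCENTRATION = 50.0


@dataclass
class GeneratorSpec:
    """Cohort-generator settings.

    Attributes
    ----------
    profiles : pandas.DataFrame
        Target mean composition per sub-CST (rows on the simplex).
    weights : pandas.Series
        Mixture weight (prevalence) per sub-CST; sums to 1.
    concentration : pandas.Series
        Dirichlet precision per sub-CST (higher = tighter around the
        profile).
    depth_range : tuple[int, int]
        Log-uniform sequencing-depth bounds (inclusive).
    seed : int
        Default master seed (overridable at generation time).
    """

    profiles: pd.DataFrame
    weights: pd.Series
    concentration: pd.Series
    depth_range: tuple[int, int] = DEFAULT_DEPTH_RANGE
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValidationError(f"mixture weights sum to {self.weights.sum()!r}, not 1")
        if (self.weights < 0).any():
            raise ValidationError("mixture weights must be non-negative")
        if not self.weights.index.equals(self.profiles.index):
            raise ValidationError("weights and profiles list different sub-CSTs")
        if not self.concentration.index.equals(self.profiles.index):
            raise ValidationError("concentration and profiles list different sub-CSTs")
        if (self.concentration <= 0).any():
            raise ValidationError("concentrations must be positive")
        sums = self.profiles.sum(axis=1)
        off = sums[(sums - 1.0).abs() > 1e-9]
        if len(off):
            raise ValidationError(f"profiles off the simplex: {dict(off.round(6))}")
        if (self.profiles.to_numpy() < 0).any():
            raise ValidationError("profiles must be non-negative")
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise ValidationError(f"bad depth range {self.depth_range!r}")

    @property
    def labels(self) -> list[str]:
        return list(self.profiles.index)

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "taxa": list(self.profiles.columns),
            "profiles": {l: self.profiles.loc[l].tolist() for l in self.profiles.index},
            "weights": {l: float(self.weights[l]) for l in self.weights.index},
            "concentration": {
                l: float(self.concentration[l]) for l in self.concentration.index
            },
            "depth_range": list(self.depth_range),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorSpec":
        taxa = list(d["taxa"])
        labels = list(d["profiles"])
        profiles = pd.DataFrame(
            [d["profiles"][l] for l in labels], index=labels, columns=taxa
        )
        return cls(
            profiles=profiles,
            weights=pd.Series({l: d["weights"][l] for l in labels}),
            concentration=pd.Series({l: d["concentration"][l] for l in labels}),
            depth_range=tuple(d["depth_range"]),
            seed=int(d.get("seed", 0)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class LabeledCohort:
    """A generated cohort: count table plus the generating truth."""

    table: CountTable
    true_labels: pd.Series
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.true_labels) != self.table.n_samples:
            raise ValidationError("true_labels and table are misaligned")


def _tail_weights(n: int, decay: float = 0.8) -> np.ndarray:
    w = decay ** np.arange(n)
    return w / w.sum()


def default_cohort_spec(
    concentration: float | dict | None = None,
    seed: int = 0,
) -> GeneratorSpec:
    """The standard 13-sub-CST generator over 12 key taxa plus a minor tail.

    Each profile's dominance structure follows the canonical sub-CST
    descriptions (I/II/III/V dominated by one Lactobacillus species, with
    V carrying 0.20 L. iners; IV-A high Ca. L. vaginae; IV-B high
    G. vaginalis; IV-C0 even with moderate Prevotella; IV-C1..C4 dominated
    by Streptococcus/Enterococcus/Bifidobacterium/Staphylococcus). The
    remainder of each profile is spread over a 20-taxon minor tail with
    geometric decay.
    """
    taxa = list(pt.KEY_TAXA) + list(MINOR_TAXA)
    tail = _tail_weights(len(MINOR_TAXA))
    rows = {}
    for label, core in _PROFILE_CORES.items():
        row = pd.Series(0.0, index=taxa)
        for taxon, value in core.items():
            row[taxon] = value
        remainder = 1.0 - row.sum()
        row[list(MINOR_TAXA)] = remainder * tail
        rows[label] = row
    profiles = pd.DataFrame(rows).T
    labels = list(profiles.index)
    weights = pd.Series({l: _DEFAULT_WEIGHTS[l] for l in labels})
    if concentration is None:
        conc = pd.Series(DEFAULT_CONCENTRATION, index=labels, dtype=float)
    elif isinstance(concentration, dict):
        conc = pd.Series(concentration, dtype=float).reindex(labels)
    else:
        conc = pd.Series(float(concentration), index=labels)
    return GeneratorSpec(
        profiles=profiles, weights=weights, concentration=conc, seed=seed
    )


def three_group_spec(concentration: float = 100.0, seed: int = 0) -> GeneratorSpec:
    """A minimal three-blob generator with disjoint dominant taxa.

    Used to exercise cluster-number selection: three groups, each a
    two-taxon community on its own pair of taxa, so the Bray-Curtis
    structure is unambiguous.
    """
    taxa = [
        pt.L_CRISPATUS,
        "g_Megasphaera",
        pt.L_INERS,
        "g_Dialister",
        pt.STREPTOCOCCUS,
        "g_Anaerococcus",
    ]
    profiles = pd.DataFrame(
        [
            [0.8, 0.2, 0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.8, 0.2, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0, 0.8, 0.2],
        ],
        index=["A", "B", "C"],
        columns=taxa,
    )
    weights = pd.Series(1 / 3, index=profiles.index)
    conc = pd.Series(float(concentration), index=profiles.index)
    return GeneratorSpec(
        profiles=profiles,
        weights=weights,
        concentration=conc,
        depth_range=(2000, 20000),
        seed=seed,
    )


def generate_cohort(
    spec: GeneratorSpec,
    n: int,
    seed: int | None = None,
) -> LabeledCohort:
    """Draw *n* samples from the generator.

    Per-sample: sub-CST ~ mixture weights; composition ~ Dirichlet
    (concentration x profile, restricted to the profile's support); depth
    ~ log-uniform over ``depth_range``; counts ~ multinomial(depth,
    composition). Row sums of the count table equal the drawn depths
    exactly, and the ``read_count`` column is set to them.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    spec.validate()
    master = spec.seed if seed is None else seed
    streams = np.random.SeedSequence(master).spawn(4)
    rng_label, rng_comp, rng_depth, rng_count = (
        np.random.default_rng(s) for s in streams
    )

    labels = np.array(spec.labels)
    drawn = rng_label.choice(labels, size=n, p=spec.weights.to_numpy())

    taxa = list(spec.profiles.columns)
    comps = np.zeros((n, len(taxa)))
    for i, label in enumerate(drawn):
        alpha = spec.concentration[label] * spec.profiles.loc[label].to_numpy()
        support = alpha > 0
        comps[i, support] = rng_comp.dirichlet(alpha[support])

    lo, hi = spec.depth_range
    depths = np.exp(
        rng_depth.uniform(np.log(lo), np.log(hi), size=n)
    ).round().astype(np.int64)
    depths = np.clip(depths, lo, hi)

    counts = np.empty((n, len(taxa)), dtype=np.int64)
    for i in range(n):
        counts[i] = rng_count.multinomial(depths[i], comps[i])

    ids = pd.Index([f"S{i + 1:05d}" for i in range(n)], name="sampleID")
    table = CountTable(
        counts=pd.DataFrame(counts, index=ids, columns=taxa),
        declared_totals=pd.Series(depths, index=ids, name="read_count"),
    )
    return LabeledCohort(table=table, true_labels=pd.Series(drawn, index=ids, name="subCST"))


# ---------------------------------------------------------------------------
# label-conditional clinical metadata
# ---------------------------------------------------------------------------

#: pH bin -> continuous range the synthetic measurement is drawn from
#: (uniform within bin, safely inside the bin edges).
_PH_VALUE_RANGES = {
    PH_CATEGORIES[0]: (3.8, 4.5),
    PH_CATEGORIES[1]: (4.55, 4.95),
    PH_CATEGORIES[2]: (5.0, 5.5),
    PH_CATEGORIES[3]: (5.55, 6.8),
}
_NUGENT_VALUE_RANGES = {
    NUGENT_CATEGORIES[0]: (0, 3),
    NUGENT_CATEGORIES[1]: (4, 7),
    NUGENT_CATEGORIES[2]: (8, 10),
}


def _split_rest(p_low: float, shares: tuple[float, float, float]) -> dict[str, float]:
    rest = 1.0 - p_low
    return {
        PH_CATEGORIES[0]: p_low,
        PH_CATEGORIES[1]: rest * shares[0],
        PH_CATEGORIES[2]: rest * shares[1],
        PH_CATEGORIES[3]: rest * shares[2],
    }


def default_metadata_rules() -> dict:
    """Plausible per-sub-CST pH and Nugent category probabilities.

    The probability of pH <= 4.5 per sub-CST follows the published cohort
    characterization (I-A 0.83, III-A 0.61, V 0.61, IV-C0 0.24, IV-C1
    0.15, IV-C2 0.42, IV-C3 0.28, IV-C4 0.39); values for the remaining
    types are plausible interpolations. Nugent categories reflect that
    Lactobacillus-dominated communities score low and IV-A/IV-B score
    high.
    """
    lacto_shares = (0.6, 0.3, 0.1)
    anaerobe_shares = (0.2, 0.3, 0.5)
    ph = {
        "I-A": _split_rest(0.83, lacto_shares),
        "I-B": _split_rest(0.70, lacto_shares),
        "II": _split_rest(0.50, lacto_shares),
        "III-A": _split_rest(0.61, lacto_shares),
        "III-B": _split_rest(0.55, lacto_shares),
        "IV-A": _split_rest(0.10, anaerobe_shares),
        "IV-B": _split_rest(0.15, anaerobe_shares),
        "IV-C0": _split_rest(0.24, anaerobe_shares),
        "IV-C1": _split_rest(0.15, anaerobe_shares),
        "IV-C2": _split_rest(0.42, anaerobe_shares),
        "IV-C3": _split_rest(0.28, anaerobe_shares),
        "IV-C4": _split_rest(0.39, anaerobe_shares),
        "V": _split_rest(0.61, lacto_shares),
    }
    lacto_nugent = {"low": 0.85, "intermediate": 0.12, "high": 0.03}
    nugent = {
        "I-A": lacto_nugent,
        "I-B": lacto_nugent,
        "II": lacto_nugent,
        "III-A": lacto_nugent,
        "III-B": {"low": 0.70, "intermediate": 0.20, "high": 0.10},
        "IV-A": {"low": 0.02, "intermediate": 0.18, "high": 0.80},
        "IV-B": {"low": 0.05, "intermediate": 0.25, "high": 0.70},
        "IV-C0": {"low": 0.20, "intermediate": 0.50, "high": 0.30},
        "IV-C1": {"low": 0.30, "intermediate": 0.50, "high": 0.20},
        "IV-C2": {"low": 0.60, "intermediate": 0.30, "high": 0.10},
        "IV-C3": {"low": 0.40, "intermediate": 0.40, "high": 0.20},
        "IV-C4": {"low": 0.60, "intermediate": 0.30, "high": 0.10},
        "V": lacto_nugent,
    }
    return {
        label: {"ph": ph[label], "nugent": nugent[label]} for label in ph
    }


def attach_metadata(
    cohort: LabeledCohort,
    rules: dict | None = None,
    seed: int = 0,
) -> LabeledCohort:
    """Attach label-conditional pH and Nugent draws to a cohort.

    *rules* maps each sub-CST present in the cohort to category
    probabilities (``{"ph": {bin: p}, "nugent": {cat: p}}``); a continuous
    pH and an integer Nugent score are then drawn uniformly within the
    drawn category. Raises if a present label has no rule.
    """
    if rules is None:
        rules = default_metadata_rules()
    present = set(cohort.true_labels.unique())
    missing = sorted(present - set(rules))
    if missing:
        raise ValidationError(f"no metadata rule for labels: {missing}")
    if cohort.table.n_samples == 0:
        return LabeledCohort(cohort.table, cohort.true_labels, pd.DataFrame())

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ph_vals, nugent_vals, ph_bins, nugent_bins = [], [], [], []
    for label in cohort.true_labels:
        rule = rules[label]
        bins = list(rule["ph"])
        probs = np.array([rule["ph"][b] for b in bins], dtype=float)
        b = rng.choice(bins, p=probs / probs.sum())
        lo, hi = _PH_VALUE_RANGES[b]
        ph_bins.append(b)
        ph_vals.append(float(rng.uniform(lo, hi)))
        cats = list(rule["nugent"])
        probs = np.array([rule["nugent"][c] for c in cats], dtype=float)
        c = rng.choice(cats, p=probs / probs.sum())
        lo_n, hi_n = _NUGENT_VALUE_RANGES[c]
        nugent_bins.append(c)
        nugent_vals.append(int(rng.integers(lo_n, hi_n + 1)))
    metadata = pd.DataFrame(
        {
            "ph": ph_vals,
            "ph_category": ph_bins,
            "nugent": nugent_vals,
            "nugent_category": nugent_bins,
        },
        index=cohort.true_labels.index,
    )
    return LabeledCohort(cohort.table, cohort.true_labels, metadata)
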