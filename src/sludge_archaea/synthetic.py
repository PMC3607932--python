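"""Synthetic inputs with controlled ground truth.

Everything the downstream pipeline consumes can be generated here at desk
scale: reference taxa whose restriction-site positions (and hence terminal
restriction fragment lengths) are planted and therefore known exactly, clone
libraries drawn from a skewed abundance distribution, replicate
electropherogram peak tables with size-calling drift, sub-threshold spurious
peaks and multiplicative height noise, plant-parameter time series with
planted linear effects on taxon abundances, and three-channel FISH label
images with a planted archaeal area fraction.

The emulated community mirrors an activated-sludge Archaea assemblage: a few
dominant acetoclastic-methanogen-like taxa over a long singleton tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .digest import ALUI, ARCH18F, RSAI, DigestStatus, EnzymeSpec, predict_trf

_BASES = np.array(list("ACGT"))

#: Concrete (non-degenerate) instantiation of the forward primer used when
#: synthesizing sequences; Y is resolved to C.
_PRIMER_CONCRETE = ARCH18F.sequence.replace("Y", "C")

#: Default parameter ranges for the plant time series (mean, spread), chosen
#: to emulate a large municipal plant: temperature degC, sludge retention time
#: d, food-to-microorganism ratio kgBOD/kgSS/d, chemical oxygen demand mg/L,
#: oxidized nitrogen mg/L, stirred sludge volume index mL/g, shear sensitivity
#: (relative turbidity increase), extracellular-polymer protein and
#: carbohydrate mg/gSS, effluent non-settleable solids mg/L.
PARAMETER_RANGES: dict[str, tuple[float, float]] = {
    "temperature": (15.0, 3.0),
    "srt": (3.0, 1.0),
    "fm_ratio": (0.008, 0.002),
    "cod": (1058.0, 240.0),
    "no23_n": (48.0, 8.0),
    "ssvi": (80.0, 15.0),
    "shear_sensitivity": (20.0, 5.0),
    "eps_protein": (30.0, 10.0),
    "eps_carbohydrate": (10.0, 4.0),
    "effluent_nss": (23.0, 10.0),
}


class ScenarioError(ValueError):
    """Raised for an internally inconsistent community scenario."""


@dataclass(frozen=True)
class ReferenceTaxon:
    """A reference organism with a planted-site 16S sequence.

    ``true_trf`` maps enzyme name to the exact labeled-fragment length that an
    in-silico digest of ``sequence`` yields — the ground truth every
    downstream size measurement is compared against.
    """

    taxon_id: str
    name: str
    sequence: str
    true_trf: Mapping[str, int]


@dataclass
class CommunityScenario:
    """A fully specified synthetic community and measurement setup.

    drift
        Bases subtracted from the true TRF when rendering observed peaks,
        emulating the systematic bias of capillary size calling (predicted
        TRFs run a few bases longer than observed ones).
    noise_sd
        Relative (multiplicative) standard deviation of peak heights.
    spurious_rate
        Poisson mean of sub-threshold noise peaks per rendered profile.
    """

    taxa: Sequence[ReferenceTaxon]
    abundance_weights: Sequence[float]
    drift: int = 5
    noise_sd: float = 0.05
    n_replicates: int = 3
    seed: int = 0
    sample_id: str = "S1"
    spurious_rate: float = 2.0
    signal_range: tuple[float, float] = (800.0, 3000.0)

    def __post_init__(self) -> None:
        w = np.asarray(self.abundance_weights, dtype=float)
        if len(w) != len(self.taxa):
            raise ScenarioError("one weight per taxon required")
        if (w < 0).any():
            raise ScenarioError("abundance weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ScenarioError("abundance weights must sum to 1")
        if self.n_replicates < 1:
            raise ScenarioError("need at least one replicate")
        if self.drift < 0:
            raise ScenarioError("drift must be non-negative")


def _clean_background(rng: np.random.Generator, length: int,
                      forbidden: Sequence[str]) -> list[str]:
    """Random sequence containing no occurrence of any forbidden motif."""
    seq = list(rng.choice(_BASES, size=length))
    changed = True
    while changed:
        changed = False
        s = "".join(seq)
        for motif in forbidden:
            pos = s.find(motif)
            if pos >= 0:
                # Mutate one base inside the occurrence to break it.
                j = pos + len(motif) // 2
                alternatives = [b for b in "ACGT" if b != seq[j]]
                seq[j] = str(rng.choice(alternatives))
                changed = True
                break
    return seq


def make_reference_taxa(n_taxa: int, seed: int, seq_length: int = 320) -> list[ReferenceTaxon]:
    """Generate taxa with exactly one AluI and one RsaI site each.

    Sites are planted at controlled, taxon-distinct positions at least 60
    bases from the labeled end, so every taxon has a unique (AluI, RsaI)
    fragment-length pair.  Deterministic for a fixed seed.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    rng = np.random.default_rng(seed)
    sites = {ALUI.name: ALUI, RSAI.name: RSAI}
    motifs = [e.recognition for e in sites.values()]
    taxa: list[ReferenceTaxon] = []
    for i in range(n_taxa):
        # Distinct planted TRF lengths per taxon; both >= 62 so the cut is at
        # least 60 bases from the labeled end and inside the sizing window.
        alui_trf = 70 + 13 * i
        rsai_trf = 96 + 17 * i
        a_pos = alui_trf - ALUI.cut_offset
        r_pos = rsai_trf - RSAI.cut_offset
        length = max(seq_length, r_pos + 40)
        for _attempt in range(100):
            seq = _clean_background(rng, length, motifs)
            seq[: len(_PRIMER_CONCRETE)] = list(_PRIMER_CONCRETE)
            seq[a_pos : a_pos + 4] = list(ALUI.recognition)
            seq[r_pos : r_pos + 4] = list(RSAI.recognition)
            s = "".join(seq)
            if s.count(ALUI.recognition) == 1 and s.count(RSAI.recognition) == 1:
                break
        else:  # pragma: no cover - overlap geometry makes this unreachable
            raise RuntimeError("could not place unique restriction sites")
        true_trf = {name: predict_trf(s, enz).length for name, enz in sites.items()}
        assert true_trf == {ALUI.name: alui_trf, RSAI.name: rsai_trf}
        taxa.append(
            ReferenceTaxon(
                taxon_id=f"T{i + 1:02d}",
                name=f"Synthetic archaeon {i + 1}",
                sequence=s,
                true_trf=true_trf,
            )
        )
    return taxa


def skewed_weights(n_taxa: int, dominance: float = 1.5) -> np.ndarray:
    """A few-dominants-plus-rare-tail abundance profile (normalized Zipf-like)."""
    ranks = np.arange(1, n_taxa + 1, dtype=float)
    w = ranks ** (-dominance)
    return w / w.sum()


def sample_clone_library(scenario: CommunityScenario, n_clones: int,
                         seed: Optional[int] = None) -> list[str]:
    """Draw a clone library: a multinomial sample of taxon ids."""
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    ids = [t.taxon_id for t in scenario.taxa]
    counts = rng.multinomial(n_clones, np.asarray(scenario.abundance_weights, float))
    library: list[str] = []
    for taxon_id, c in zip(ids, counts):
        library.extend([taxon_id] * int(c))
    rng.shuffle(library)
    return library


# Peak-table column order of the emulated capillary-electrophoresis export.
PEAK_TABLE_COLUMNS = ["sample_id", "enzyme", "replicate", "size_bases", "height_fu", "area"]


def render_electropherograms(scenario: CommunityScenario):
    """Render one raw peak profile per replicate x enzyme.

    Each taxon with weight w contributes a peak at size (true TRF - drift)
    with height w*H*(1+eps), where H is a per-replicate total-signal factor
    drawn uniformly from ``signal_range`` and eps ~ Normal(0, noise_sd).
    Spurious sub-threshold peaks (heights 10-49 FU) are added at a Poisson
    rate.  Heights are clipped at zero; non-positive peaks are dropped.
    """
    from .trflp import Peak, RawProfile

    rng = np.random.default_rng(scenario.seed)
    enzymes = sorted(scenario.taxa[0].true_trf) if scenario.taxa else []
    profiles: list[RawProfile] = []
    for rep in range(1, scenario.n_replicates + 1):
        h_total = rng.uniform(*scenario.signal_range)
        for enzyme in enzymes:
            peaks = []
            for taxon, w in zip(scenario.taxa, scenario.abundance_weights):
                if w <= 0:
                    continue
                size = float(taxon.true_trf[enzyme] - scenario.drift)
                eps = rng.normal(0.0, scenario.noise_sd) if scenario.noise_sd > 0 else 0.0
                height = max(0.0, w * h_total * (1.0 + eps))
                if height > 0:
                    peaks.append(Peak(size=size, height=height, area=height))
            n_spurious = rng.poisson(scenario.spurious_rate) if scenario.spurious_rate > 0 else 0
            for _ in range(n_spurious):
                h = rng.uniform(10.0, 49.0)
                peaks.append(Peak(size=rng.uniform(50.0, 1020.0), height=h, area=h))
            peaks.sort(key=lambda p: p.size)
            profiles.append(
                RawProfile(
                    sample_id=scenario.sample_id,
                    enzyme=enzyme,
                    replicate_id=rep,
                    peaks=peaks,
                )
            )
    return profiles


def generate_parameter_series(
    n_samples: int,
    planted_effects: Mapping[str, tuple[str, float]],
    seed: int,
    taxon_ids: Optional[Sequence[str]] = None,
    base_abundance: float = 0.5,
    noise_sd: float = 0.0,
    start_date: str = "2003-05-16",
):
    """Plant-parameter time series with linear taxon-abundance couplings.

    Returns ``(parameters, abundances, true_slopes)``: a parameter table and a
    per-taxon abundance table, both indexed by ISO sample dates, plus the
    ground-truth slope per planted taxon.  A planted effect couples a taxon's
    abundance linearly to one parameter (centred), plus Gaussian noise;
    abundances are deliberately not renormalized across taxa, which would
    destroy the planted linearity.
    """
    import pandas as pd

    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    for taxon_id, (param, _slope) in planted_effects.items():
        if param not in PARAMETER_RANGES:
            raise KeyError(f"unknown parameter {param!r} for taxon {taxon_id!r}")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start_date, periods=n_samples, freq="14D")
    params = pd.DataFrame(
        {
            name: rng.uniform(mean - spread, mean + spread, size=n_samples)
            for name, (mean, spread) in PARAMETER_RANGES.items()
        },
        index=dates,
    )
    if taxon_ids is None:
        taxon_ids = sorted(planted_effects)
    abundances = pd.DataFrame(index=dates, columns=list(taxon_ids), dtype=float)
    true_slopes: dict[str, float] = {}
    for taxon_id in taxon_ids:
        if taxon_id in planted_effects:
            param, slope = planted_effects[taxon_id]
            x = params[param].to_numpy()
            centred = x - x.mean()
            y = base_abundance + slope * centred
            true_slopes[taxon_id] = slope
        else:
            y = np.full(n_samples, base_abundance)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=n_samples)
        abundances[taxon_id] = np.clip(y, 0.0, None)
    return params, abundances, true_slopes


def make_label_image_set(
    shape: tuple[int, int],
    frac_archaea: float,
    seed: int,
    coverage: float = 0.3,
    intensity: int = 200,
    frac_double: float = 0.0,
):
    """Three-channel FISH label rasters with a planted archaeal area fraction.

    A ``coverage`` fraction of pixels carries signal; of those, ``frac_archaea``
    are archaeal (split between the general-archaeal and the
    Methanosaetaceae-specific channel) and the rest bacterial.  ``frac_double``
    of signal pixels are lit in both the bacterial and an archaeal channel
    (hybridization artefacts that quantification must discard).
    """
    if not 0.0 <= frac_archaea <= 1.0:
        raise ValueError("frac_archaea must be within [0, 1]")
    rng = np.random.default_rng(seed)
    n_pix = shape[0] * shape[1]
    n_signal = int(round(coverage * n_pix))
    idx = rng.choice(n_pix, size=n_signal, replace=False)
    n_arch = int(round(frac_archaea * n_signal))
    n_double = int(round(frac_double * n_signal))
    arch_idx = idx[:n_arch]
    bact_idx = idx[n_arch:]
    eub = np.zeros(n_pix, dtype=np.uint8)
    arc = np.zeros(n_pix, dtype=np.uint8)
    mx = np.zeros(n_pix, dtype=np.uint8)
    eub[bact_idx] = intensity
    # Half the archaeal pixels are lit in the universal channel, half only in
    # the Methanosaetaceae channel (the universal probe misses some cells).
    half = n_arch // 2
    arc[arch_idx[:half]] = intensity
    mx[arch_idx[half:]] = intensity
    mx[arch_idx[: half // 2]] = intensity  # overlap: MX also covers some ARC pixels
    if n_double > 0:
        dbl = rng.choice(idx, size=min(n_double, n_signal), replace=False)
        eub[dbl] = intensity
        arc[dbl] = intensity
    return {
        "EUB": eub.reshape(shape),
        "ARC915": arc.reshape(shape),
        "MX825": mx.reshape(shape),
    }


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_reference_fasta(taxa: Sequence[ReferenceTaxon], path) -> None:
    """Write reference taxa as FASTA (taxon name in the description)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(t.sequence), id=t.taxon_id, description=t.name) for t in taxa
    ]
    SeqIO.write(records, str(path), "fasta")


def write_peak_table(profiles, path) -> None:
    """Write raw profiles as the CSV peak-table dialect the pipeline reads."""
    import pandas as pd

    rows = [
        {
            "sample_id": p.sample_id,
            "enzyme": p.enzyme,
            "replicate": p.replicate_id,
            "size_bases": peak.size,
            "height_fu": peak.height,
            "area": peak.area,
        }
        for p in profiles
        for peak in p.peaks
    ]
    pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS).to_csv(path, index=False)


def write_parameter_series(params, path) -> None:
    """Write the parameter table with an ISO-8601 ``date`` index column."""
    out = params.copy()
    out.index.name = "date"
    out.to_csv(path, date_format="%Y-%m-%d")


def scenario_to_yaml(scenario: CommunityScenario, path) -> None:
    """Describe a scenario (minus sequences) in a key-value config file."""
    doc = {
        "sample_id": scenario.sample_id,
        "taxa": [
            {"taxon_id": t.taxon_id, "name": t.name, "true_trf": dict(t.true_trf)}
            for t in scenario.taxa
        ],
        "abundance_weights": [float(w) for w in scenario.abundance_weights],
        "drift": scenario.drift,
        "noise_sd": scenario.noise_sd,
        "n_replicates": scenario.n_replicates,
        "seed": scenario.seed,
        "spurious_rate": scenario.spurious_rate,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
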