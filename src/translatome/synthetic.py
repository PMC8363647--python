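"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study conditions end to end:

* **Transcripts** — per-gene 5'UTR/CDS/3'UTR sequences with planted
  TOP/TOP-like motifs, uORFs, AU-rich elements, TISU context and a
  controllable 5'UTR length/structure, verified against the default scanners
  so that every planted flag is confirmed exactly.
* **Two-colour arrays** — eight tumour samples vs two controls, three
  repeats each, with dye swaps; observed intensity is additive normal
  background plus exponential signal, which makes the normexp correction in
  :mod:`translatome.preprocess` exactly well-specified on synthetic data.
  A fraction of genes carries a shifted polysome/subpolysome log-ratio.
* **Particle fields** — label images of non-overlapping rasterised ellipses
  whose continuous axes are drawn to satisfy a known morphology class
  (elongated / enlarged / other).

One global seed expands into fixed per-component substreams so components
can be re-run independently and reproducibly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from . import seqfeatures as sf
from .preprocess import ArrayExperiment

logger = logging.getLogger(__name__)

# fixed substream offsets for the per-component generators
_STREAM_TRANSCRIPTS = 1
_STREAM_ARRAYS = 2
_STREAM_PARTICLES = 3
_STREAM_GO = 4

PURINES = "AG"
# stop- and ATG-free codons that also avoid creating ATG or stop codons at
# any junction with each other (first chars exclude A, last two never 'AT')
SAFE_CODONS = ("GCA", "CAC", "GAC", "GGA", "CTG", "CCA", "GAA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in sf.STOP_CODONS
)
_HAIRPIN = "GCGCGCGC" + "AAAA" + "GCGCGCGC"  # self-complementary 8-bp stem


class FeasibilityError(ValueError):
    """A planted feature cannot fit in the requested sequence."""


@dataclass
class SimulationDesign:
    """Design of the synthetic polysome-profiling experiment."""

    n_genes: int = 500
    n_tumour_samples: int = 8
    n_control_samples: int = 2
    n_repeats: int = 3
    dye_swap_repeats: tuple[int, ...] = (1,)  # 0-based repeat indices swapped
    frac_up: float = 0.1
    frac_down: float = 0.05
    effect_log2: float = 2.0
    noise_sd: float = 0.5
    background_mean: float = 100.0
    background_sd: float = 15.0
    signal_rate: float = 1000.0  # mean of the exponential signal component
    abundance_sigma: float = 0.0  # log-normal per-gene baseline spread (off)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_tumour_samples", "n_control_samples", "n_repeats"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.frac_up and 0 <= self.frac_down):
            raise ValueError("planted fractions must be >= 0")
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must be <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.background_sd <= 0 or self.signal_rate <= 0:
            raise ValueError("background_sd and signal_rate must be > 0")
        if any(r < 0 or r >= self.n_repeats for r in self.dye_swap_repeats):
            raise ValueError("dye_swap_repeats out of range")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i + 1:0{width}d}" for i in range(self.n_genes)]


@dataclass
class FeatureSpec:
    """Feature probabilities and length distributions for one gene class."""

    p_top: float = 0.05
    p_top_like: float = 0.05
    p_uorf: float = 0.45
    max_uorf: int = 2
    p_are: float = 0.30
    max_are: int = 2
    p_tisu: float = 0.05
    p_structured: float = 0.5
    utr5_len_mean: float = 150.0
    utr5_len_sd: float = 40.0
    utr5_len_min: int = 20
    utr5_len_max: int | None = None  # hard cap; planted features must fit
    utr3_len_mean: float = 250.0
    utr3_len_sd: float = 80.0
    utr3_len_min: int = 30
    cds_codons_min: int = 40
    cds_codons_max: int = 100

    def __post_init__(self) -> None:
        for name in ("p_top", "p_top_like", "p_uorf", "p_are", "p_tisu", "p_structured"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_top + self.p_top_like > 1:
            raise ValueError("p_top + p_top_like must be <= 1")
        for name in ("utr5_len_mean", "utr5_len_sd", "utr3_len_mean", "utr3_len_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def default_feature_specs() -> dict[str, FeatureSpec]:
    """Class-conditional feature distributions.

    Translationally upregulated genes carry shorter, less structured 5'UTRs
    with fewer uORFs and more TISU elements than the array background; TOP
    and ARE rates are class-independent.
    """
    null = FeatureSpec()
    up = replace(
        null,
        utr5_len_mean=70.0,
        utr5_len_sd=30.0,
        p_uorf=0.15,
        p_tisu=0.15,
        p_structured=0.2,
    )
    return {"up": up, "down": null, "null": null}


@dataclass
class PlantedTruth:
    """Ground truth of a synthetic experiment.

    ``regulation`` maps each gene to ``up``/``down``/``null``; ``features``
    (filled by :func:`gen_transcripts`) records the planted sequence features
    per gene.
    """

    regulation: pd.Series
    features: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.regulation.index.duplicated().any():
            raise ValueError("duplicate gene ids in truth")
        bad = set(self.regulation.unique()) - {"up", "down", "null"}
        if bad:
            raise ValueError(f"invalid regulation classes: {sorted(bad)}")


def assign_regulation(design: SimulationDesign) -> PlantedTruth:
    """Assign up/down/null classes to genes (counts match the design)."""
    rng = np.random.default_rng([design.seed, _STREAM_TRANSCRIPTS, 0])
    genes = design.gene_ids()
    n_up = int(round(design.frac_up * design.n_genes))
    n_down = int(round(design.frac_down * design.n_genes))
    labels = np.array(
        ["up"] * n_up + ["down"] * n_down + ["null"] * (design.n_genes - n_up - n_down)
    )
    rng.shuffle(labels)
    return PlantedTruth(regulation=pd.Series(labels, index=genes, name="regulation"))


# --- transcript assembly ----------------------------------------------------


def _rand_seq(rng, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n)) if n > 0 else ""


def _scrub_atg(s: str) -> str:
    """Destroy every ATG in a segment (ATG -> ACG cannot recreate ATG)."""
    while "ATG" in s:
        i = s.index("ATG")
        s = s[:i] + "ACG" + s[i + 3 :]
    return s


def _top_prefix(rng, top_class: str, min_run: int) -> str:
    """A 5' prefix that forces the requested TOP class."""
    if top_class == "TOP":
        return "C" + _rand_seq(rng, min_run, sf.PYRIMIDINES)
    if top_class == "TOP_like":
        offset = int(rng.integers(1, 5))  # pattern starts at 1-based pos 2..5
        return _rand_seq(rng, offset, PURINES) + "C" + _rand_seq(rng, min_run, sf.PYRIMIDINES)
    # purines at positions 1-5 rule out both TOP and TOP-like
    return _rand_seq(rng, 5, PURINES)


def _uorf_cassette(rng, min_len: int = 9) -> str:
    n_extra = int(rng.integers(1, 4))
    body = "".join(rng.choice(SAFE_CODONS, size=n_extra))
    cas = "ATG" + body + "TAA"
    assert len(cas) >= min_len
    return cas


def _build_utr5(
    rng, gene: str, length: int, top_class: str, n_uorf: int, structured: bool,
    tisu_context: bool, min_top_run: int, len_cap: int | None = None,
) -> str:
    """Assemble a 5'UTR of at least ``length`` nt holding the planted blocks.

    The drawn length is a target minimum: if the planted blocks need more
    room the UTR grows to fit them, unless that exceeds ``len_cap`` (an
    explicit per-class cap), which raises a feasibility error naming the
    gene.
    """
    prefix = _top_prefix(rng, top_class, min_top_run)
    segments = []
    if structured:
        segments.append(_HAIRPIN)
    cassettes = [_uorf_cassette(rng) for _ in range(n_uorf)]
    segments.extend(cassettes)
    tail = 4 if tisu_context else 0
    needed = len(prefix) + sum(len(s) for s in segments) + tail
    if len_cap is not None and needed > len_cap:
        raise FeasibilityError(
            f"{gene}: 5'UTR capped at {len_cap} nt cannot hold the planted "
            f"features (need >= {needed} nt)"
        )
    length = max(length, needed)
    # split the remaining length into random filler gaps around the segments
    free = length - needed
    n_gaps = len(segments) + 1
    cuts = np.sort(rng.integers(0, free + 1, size=n_gaps - 1)) if n_gaps > 1 else []
    gaps = np.diff(np.concatenate([[0], cuts, [free]])).astype(int)
    parts = [prefix]
    for seg, gap in zip(segments, gaps[:-1]):
        parts.append(_scrub_atg(_rand_seq(rng, int(gap))))
        parts.append(seg)
    parts.append(_scrub_atg(_rand_seq(rng, int(gaps[-1]) + tail)))
    u = "".join(parts)
    if tisu_context:
        s1, s2 = rng.choice(list("GC"), size=2)
        u = u[:-4] + s1 + "A" + "A" + s2
    assert len(u) == length
    return u


def _build_cds(rng, n_codons: int, tisu_context: bool) -> str:
    stop = str(rng.choice(list(sf.STOP_CODONS)))
    if tisu_context:
        head = ["ATG", "GCG", "GCA"]  # ATGGCGGC consensus core
    else:
        head = ["ATG"]
    n_body = max(n_codons - len(head) - 1, 0)
    body = list(rng.choice(_SENSE_CODONS, size=n_body))
    return "".join(head + body + [stop])


def _build_utr3(rng, gene: str, length: int, n_are: int) -> str:
    s = _rand_seq(rng, length)
    # destroy accidental ARE cores
    while "TATTTAT" in s:
        i = s.index("TATTTAT")
        s = s[:i] + "TATGTAT" + s[i + 7 :]
    if n_are == 0:
        return s
    if 9 * n_are > length:
        raise FeasibilityError(
            f"{gene}: 3'UTR of length {length} cannot hold {n_are} AU-rich elements"
        )
    # overwrite non-overlapping 9-nt windows with ARE motifs
    n_slots = min(n_are * 4, length - 8)
    slots = np.sort(rng.choice(length - 9 + 1, size=n_slots, replace=False))
    chosen: list[int] = []
    for pos in slots:
        if not chosen or pos >= chosen[-1] + 9:
            chosen.append(int(pos))
        if len(chosen) == n_are:
            break
    if len(chosen) < n_are:
        chosen = [9 * i for i in range(n_are)]  # deterministic fallback packing
    for pos in chosen:
        motif = "TATTTAT" + _rand_seq(rng, 2, "AT")
        s = s[:pos] + motif + s[pos + 9 :]
    return s


def gen_transcripts(
    design: SimulationDesign,
    feature_specs: dict[str, FeatureSpec] | None = None,
    truth: PlantedTruth | None = None,
    min_top_run: int = 4,
    plant_tisu_context: bool = True,
    max_attempts: int = 30,
) -> tuple[list[sf.TranscriptRecord], PlantedTruth]:
    """Generate transcripts with planted, scanner-verified features.

    Every planted feature is re-checked with the default scanners from
    :mod:`translatome.seqfeatures`; a gene whose sequence cannot be made to
    agree (or whose UTR cannot hold the requested features) raises an error
    naming the gene.
    """
    specs = feature_specs if feature_specs is not None else default_feature_specs()
    if truth is None:
        truth = assign_regulation(design)
    rng = np.random.default_rng([design.seed, _STREAM_TRANSCRIPTS, 1])
    records: list[sf.TranscriptRecord] = []
    rows = []
    for gene in design.gene_ids():
        cls = truth.regulation[gene]
        spec = specs[cls]
        # draw the planted feature set once per gene
        r = rng.random()
        if r < spec.p_top:
            top_class = "TOP"
        elif r < spec.p_top + spec.p_top_like:
            top_class = "TOP_like"
        else:
            top_class = "none"
        n_uorf = int(rng.integers(1, spec.max_uorf + 1)) if rng.random() < spec.p_uorf else 0
        n_are = int(rng.integers(1, spec.max_are + 1)) if rng.random() < spec.p_are else 0
        tisu = bool(rng.random() < spec.p_tisu)
        structured = bool(rng.random() < spec.p_structured)
        utr5_len = max(int(round(rng.normal(spec.utr5_len_mean, spec.utr5_len_sd))),
                       spec.utr5_len_min)
        utr3_len = max(int(round(rng.normal(spec.utr3_len_mean, spec.utr3_len_sd))),
                       spec.utr3_len_min)
        n_codons = int(rng.integers(spec.cds_codons_min, spec.cds_codons_max + 1))
        tisu_context = tisu and plant_tisu_context

        rec = None
        for _ in range(max_attempts):
            utr5 = _build_utr5(
                rng, gene, utr5_len, top_class, n_uorf, structured,
                tisu_context, min_top_run, len_cap=spec.utr5_len_max,
            )
            cds = _build_cds(rng, n_codons, tisu_context)
            utr3 = _build_utr3(rng, gene, utr3_len, n_are)
            if (
                sf.scan_top(utr5, min_run=min_top_run) == top_class
                and len(sf.find_uorfs(utr5, cds)) == n_uorf
                and sf.scan_are(utr3) == n_are
                and (not tisu_context or sf.tisu_flag(gene, utr5=utr5, cds=cds,
                                                      mode="consensus"))
            ):
                rec = sf.TranscriptRecord(gene, utr5, cds, utr3)
                break
        if rec is None:
            raise RuntimeError(f"{gene}: could not realise the planted feature set")
        records.append(rec)
        rows.append(
            {
                "gene": gene,
                "regulation": cls,
                "top_class": top_class,
                "n_uorf": n_uorf,
                "n_are": n_are,
                "tisu": tisu,
                "utr5_len": len(rec.utr5),
                "structured": structured,
            }
        )
    features = pd.DataFrame(rows).set_index("gene")
    return records, PlantedTruth(regulation=truth.regulation, features=features)


def tisu_gene_list(truth: PlantedTruth) -> list[str]:
    """Genes whose planted TISU flag is set (the synthetic curated list)."""
    if truth.features is None:
        raise ValueError("truth has no feature table")
    return list(truth.features.index[truth.features["tisu"]])


# --- two-colour arrays ------------------------------------------------------


def gen_array_experiment(
    design: SimulationDesign, truth: PlantedTruth
) -> ArrayExperiment:
    """Simulate the two-colour polysome-profiling arrays.

    Per gene and array the true log-ratio M is 0 for null genes and
    +-``effect_log2`` for planted genes on tumour arrays, plus N(0, noise_sd)
    array noise.  The shared true signal s (exponential with a log-normal
    per-gene baseline) is split as ``s * 2**(M/2)`` into the polysome channel
    and ``s * 2**(-M/2)`` into the subpolysome channel; additive truncated
    normal background is drawn per spot and channel.  Dye-swapped arrays have
    the red/green assignment exchanged.
    """
    rng = np.random.default_rng([design.seed, _STREAM_ARRAYS])
    genes = design.gene_ids()
    G = len(genes)
    reg = truth.regulation.reindex(genes)
    direction = np.where(reg == "up", 1.0, np.where(reg == "down", -1.0, 0.0))

    # per-gene baseline abundance, log-normal with unit mean
    if design.abundance_sigma > 0:
        base = rng.lognormal(-design.abundance_sigma**2 / 2, design.abundance_sigma, G)
    else:
        base = np.ones(G)

    sample_ids = [f"T{i + 1}" for i in range(design.n_tumour_samples)] + [
        f"N{i + 1}" for i in range(design.n_control_samples)
    ]
    red_cols, green_cols, meta_rows = {}, {}, []
    for sid in sample_ids:
        is_tumour = sid.startswith("T")
        for rep in range(design.n_repeats):
            aid = f"{sid}_r{rep + 1}"
            swap = rep in design.dye_swap_repeats
            true_m = direction * design.effect_log2 if is_tumour else np.zeros(G)
            m = true_m + rng.normal(0.0, design.noise_sd, G)
            s = base * rng.exponential(design.signal_rate, G)
            poly = np.maximum(rng.normal(design.background_mean, design.background_sd, G), 0.0)
            sub = np.maximum(rng.normal(design.background_mean, design.background_sd, G), 0.0)
            poly = poly + s * 2.0 ** (m / 2.0)
            sub = sub + s * 2.0 ** (-m / 2.0)
            red_cols[aid], green_cols[aid] = (sub, poly) if swap else (poly, sub)
            meta_rows.append(
                {
                    "array_id": aid,
                    "group": "tumour" if is_tumour else "control",
                    "sample_id": sid,
                    "replicate": rep + 1,
                    "dye_swap": swap,
                }
            )
    idx = pd.Index(genes, name="probe")
    return ArrayExperiment(
        red=pd.DataFrame(red_cols, index=idx),
        green=pd.DataFrame(green_cols, index=idx),
        meta=pd.DataFrame(meta_rows).set_index("array_id"),
    )


# --- particle fields --------------------------------------------------------

PARTICLE_CLASSES = ("elongated", "enlarged", "other")


def _ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's approximation for an ellipse with semi-axes a, b."""
    return np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))


def _draw_particle_params(rng, cls: str) -> tuple[float, float]:
    """Semi-axes (a >= b, in um) satisfying the class definition."""
    if cls == "elongated":
        b = rng.uniform(0.10, 0.16)
        a = b * rng.uniform(3.5, 5.0)
    elif cls == "enlarged":
        ratio = rng.uniform(1.0, 1.25)
        area = rng.uniform(0.7, 1.4)
        a = np.sqrt(area * ratio / np.pi)
        b = a / ratio
    elif cls == "other":
        ratio = rng.uniform(1.4, 2.4)
        area = rng.uniform(0.12, 0.35)
        a = np.sqrt(area * ratio / np.pi)
        b = a / ratio
    else:
        raise ValueError(f"unknown particle class {cls!r}")
    return float(a), float(b)


def gen_particle_field(
    n_fields: int = 20,
    particles_per_field: int = 17,
    class_mix: tuple[float, float, float] = (0.25, 0.35, 0.40),
    pixel_size_um: float = 0.02,
    seed: int = 0,
    field_shape_px: tuple[int, int] = (512, 512),
    max_attempts: int = 10_000,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Rasterised fields of non-overlapping elliptical particles.

    Returns one integer label grid per field and a truth table with the
    continuous parameters (semi-axes and analytic area in um^2, pixel-size
    invariant) and the class each particle was drawn to satisfy.
    """
    if abs(sum(class_mix) - 1.0) > 1e-9:
        raise ValueError("class_mix fractions must sum to 1")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    rng = np.random.default_rng([seed, _STREAM_PARTICLES])
    counts = np.floor(np.asarray(class_mix) * particles_per_field).astype(int)
    while counts.sum() < particles_per_field:
        counts[int(np.argmax(np.asarray(class_mix) * particles_per_field - counts))] += 1
    grids: list[np.ndarray] = []
    rows = []
    h, w = field_shape_px
    for f in range(n_fields):
        grid = np.zeros((h, w), dtype=np.int32)
        label = 0
        classes = [c for c, n in zip(PARTICLE_CLASSES, counts) for _ in range(n)]
        rng.shuffle(classes)
        for cls in classes:
            a_um, b_um = _draw_particle_params(rng, cls)
            a_px, b_px = a_um / pixel_size_um, b_um / pixel_size_um
            placed = False
            for _ in range(max_attempts):
                theta = rng.uniform(0, np.pi)
                margin = max(a_px, b_px) + 3
                if 2 * margin >= min(h, w):
                    break
                cy = rng.uniform(margin, h - margin)
                cx = rng.uniform(margin, w - margin)
                rr, cc = draw_ellipse(cy, cx, a_px, b_px, shape=grid.shape,
                                      rotation=theta)
                if rr.size >= 5 and not grid[rr, cc].any():
                    label += 1
                    grid[rr, cc] = label
                    rows.append(
                        {
                            "field_id": f"field{f + 1:03d}",
                            "particle_id": label,
                            "class": cls,
                            "major_axis_um": 2 * a_um,
                            "minor_axis_um": 2 * b_um,
                            "area_um2": np.pi * a_um * b_um,
                            "axis_ratio": a_um / b_um,
                            "circularity": 4 * np.pi * (np.pi * a_um * b_um)
                            / _ellipse_perimeter(a_um, b_um) ** 2,
                        }
                    )
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"field {f}: could not place a {cls} particle after "
                    f"{max_attempts} attempts; field too small"
                )
        grids.append(grid)
    truth = pd.DataFrame(rows)
    return grids, truth


# --- synthetic GO annotation ------------------------------------------------


def gen_go_map(
    truth: PlantedTruth,
    n_terms: int = 15,
    base_rate: float = 0.08,
    n_enriched_terms: int = 2,
    enrichment_factor: float = 3.0,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Synthetic gene -> GO-term annotation map.

    The first ``n_enriched_terms`` terms annotate planted up-regulated genes
    at ``enrichment_factor`` times the background rate, giving the GO
    over-representation stage a known positive control.
    """
    rng = np.random.default_rng([seed, _STREAM_GO])
    genes = list(truth.regulation.index)
    up = truth.regulation == "up"
    annot: dict[str, set[str]] = {g: set() for g in genes}
    for t in range(n_terms):
        term = f"GO:{t + 1:07d}"
        rate = np.full(len(genes), base_rate)
        if t < n_enriched_terms:
            rate[up.values] = min(base_rate * enrichment_factor, 1.0)
        hits = rng.random(len(genes)) < rate
        for g, h in zip(genes, hits):
            if h:
                annot[g].add(term)
    return {g: s for g, s in annot.items() if s}
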