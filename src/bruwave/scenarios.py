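"""Shipped simulation scenarios and plain-text scenario configs."""

from __future__ import annotations

import yaml

from .quant import GeneAnnotation
from .sim import (
    ElongationProfile,
    GeneKinetics,
    InitiationProfile,
    LabelingScheme,
    SimScenario,
)


def _gene(gene_id: str, length: int, strand: str, bin_size: int = 1000) -> GeneAnnotation:
    # one gene per chromosome, grid-aligned; minus-strand genes have TSS = end
    return GeneAnnotation(gene_id, f"chr_{gene_id}", 0, length, strand)


def pattern_cohort(n_per_pattern: int = 40, n_background: int = 0, fold: float = 3.0,
                   baseline_rate: float = 1.0, gene_length: int = 30_000,
                   rate_kb_min: float = 6.0, read_depth: float = 5.0,
                   delayed_onset: float = 60.0, noise: str = "poisson",
                   seed: int = 0) -> SimScenario:
    """Cohort with every temporal pattern represented, for classifier recovery.

    Short genes and brisk elongation keep the TSS-proximal window responsive
    within its onset labeling period. Constant background genes stabilize
    per-window library sizes so RPKM ratios track initiation-rate ratios.
    """
    patterns = [
        "constant", "sustained_up", "sustained_down", "transient_up",
        "transient_down", "delayed_up", "delayed_down", "reversal",
    ]
    genes: list[GeneKinetics] = []
    i = 0
    for pattern in patterns:
        for _ in range(n_per_pattern):
            onset = delayed_onset if pattern.startswith("delayed") else 0.0
            init = InitiationProfile.from_pattern(
                pattern, baseline_rate, fold=fold, onset=onset,
                duration=30.0, reversal_order="down_up", reversal_lag=60.0,
            )
            strand = "+" if i % 2 == 0 else "-"
            genes.append(GeneKinetics(
                _gene(f"{pattern}_{i:04d}", gene_length, strand),
                init,
                ElongationProfile.constant(rate_kb_min, gene_length),
            ))
            i += 1
    for j in range(n_background):
        strand = "+" if j % 2 == 0 else "-"
        genes.append(GeneKinetics(
            _gene(f"bg_{j:04d}", gene_length, strand),
            InitiationProfile.constant(baseline_rate),
            ElongationProfile.constant(rate_kb_min, gene_length),
        ))
    return SimScenario(tuple(genes), read_depth=read_depth, noise=noise, seed=seed)


def wave_cohort(n_genes: int = 21, direction: str = "induced",
                gene_length: int = 400_000,
                segments: tuple[tuple[float, float], ...] | None = None,
                rate_kb_min: float = 2.0, fold: float = 20.0,
                baseline_rate: float = 1.0, read_depth: float = 50.0 / 30.0,
                noise: str = "poisson", seed: int = 0,
                prefix: str | None = None) -> SimScenario:
    """Long-gene cohort with an advancing (induced) or retreating (repressed)
    transcription wave of known kinetics.

    Both directions share the same plateau read depth at matched parameters
    (``baseline_rate * window_duration * read_depth`` reads per bin): the
    repressed plateau is the starved steady state, while induced genes start
    from a ``1/fold`` baseline and step up to ``baseline_rate`` at t=0.
    """
    if segments is None:
        segments = ((float(gene_length), float(rate_kb_min)),)
    elong = ElongationProfile(tuple(segments))
    if elong.total_length < gene_length:
        raise ValueError("elongation segments shorter than gene")
    genes: list[GeneKinetics] = []
    prefix = prefix or ("ind" if direction == "induced" else "rep")
    for i in range(n_genes):
        if direction == "induced":
            # low starved baseline so the advancing wedge dominates the track
            init = InitiationProfile.from_pattern(
                "sustained_up", baseline_rate / fold, fold=fold, onset=0.0)
        elif direction == "repressed":
            init = InitiationProfile.from_pattern(
                "sustained_down", baseline_rate, fold=fold, onset=0.0)
        else:
            raise ValueError("direction must be 'induced' or 'repressed'")
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneKinetics(_gene(f"{prefix}_{i:04d}", gene_length, strand), init, elong))
    return SimScenario(tuple(genes), read_depth=read_depth, noise=noise, seed=seed)


def merge_scenarios(*scenarios: SimScenario, seed: int | None = None) -> SimScenario:
    base = scenarios[0]
    genes: list[GeneKinetics] = []
    for sc in scenarios:
        if sc.bin_size != base.bin_size or sc.noise != base.noise or sc.read_depth != base.read_depth:
            raise ValueError("scenarios must share bin_size, noise and read_depth to merge")
        genes.extend(sc.genes)
    ids = [gk.gene.gene_id for gk in genes]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate gene ids across merged scenarios")
    return SimScenario(tuple(genes), bin_size=base.bin_size, read_depth=base.read_depth,
                       seed=base.seed if seed is None else seed, noise=base.noise,
                       scheme=base.scheme)


def default_scenario(seed: int = 0, noise: str = "poisson") -> SimScenario:
    """The shipped default: pattern genes plus background plus long wave genes."""
    patterns = pattern_cohort(n_per_pattern=5, n_background=40, read_depth=5.0,
                              noise=noise, seed=seed)
    ind = wave_cohort(3, "induced", read_depth=5.0, noise=noise, seed=seed)
    rep = wave_cohort(3, "repressed", read_depth=5.0, noise=noise, seed=seed)
    return merge_scenarios(patterns, ind, rep, seed=seed)


PRESETS = {
    "default": default_scenario,
    "patterns": lambda seed=0, noise="poisson": pattern_cohort(seed=seed, noise=noise, n_background=1280),
    "waves": lambda seed=0, noise="poisson": merge_scenarios(
        wave_cohort(21, "induced", seed=seed, noise=noise, read_depth=5.0),
        wave_cohort(21, "repressed", seed=seed, noise=noise, read_depth=5.0),
        seed=seed,
    ),
}


# ---------------------------------------------------------------------------
# Plain-text scenario config
# ---------------------------------------------------------------------------


def load_scenario(path) -> SimScenario:
    """Load a scenario from a YAML config file.

    Schema: top-level bin_size/read_depth/noise/seed, optional
    ``windows: [[name, start, end], ...]``, and a ``genes`` list with
    per-gene annotation, initiation pattern and elongation segments.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "genes" not in cfg:
        raise ValueError(f"scenario config {path} must define a 'genes' list")
    scheme = LabelingScheme.default()
    if "windows" in cfg:
        scheme = LabelingScheme(tuple((str(n), float(s), float(e)) for n, s, e in cfg["windows"]))
    genes: list[GeneKinetics] = []
    for entry in cfg["genes"]:
        gene = GeneAnnotation(str(entry["id"]), str(entry["chrom"]),
                              int(entry["start"]), int(entry["end"]), str(entry["strand"]))
        if "elongation" in entry:
            elong = ElongationProfile(tuple((float(l), float(r)) for l, r in entry["elongation"]))
        else:
            elong = ElongationProfile.constant(float(entry.get("rate_kb_min", 2.0)), gene.length)
        init = InitiationProfile.from_pattern(
            str(entry.get("pattern", "constant")),
            float(entry.get("baseline_rate", 1.0)),
            fold=float(entry.get("fold", 3.0)),
            onset=float(entry.get("onset", 0.0)),
            duration=float(entry.get("duration", 30.0)),
            reversal_order=str(entry.get("reversal_order", "down_up")),
            reversal_lag=float(entry.get("reversal_lag", 60.0)),
        ) if entry.get("pattern", "constant") != "constant" else InitiationProfile.constant(
            float(entry.get("baseline_rate", 1.0)))
        genes.append(GeneKinetics(gene, init, elong))
    return SimScenario(
        tuple(genes),
        bin_size=int(cfg.get("bin_size", 1000)),
        read_depth=float(cfg.get("read_depth", 1.0)),
        seed=int(cfg.get("seed", 0)),
        noise=str(cfg.get("noise", "poisson")),
        scheme=scheme,
    )
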