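"""Seeded synthetic inputs with planted truth.

The generator emulates the statistical structure the pipeline assumes:
coverage tracks with a planted piecewise-constant regional mean,
localized enhancer-dense regions where an H3K27ac-like and an ATAC-like
track are jointly boosted, and a contact-score track where bin pairs
linking the members of planted 3D hubs carry elevated scores over a
distance-decaying background.  Everything is deterministic under the
spec's seed, and small enough for exhaustive oracles.

Two deliberate simplifications (see docs/methods.md): the regional mean
structure is carried by the non-mark tracks only, so the joint
enhancer-bin call stays specific to the planted enhancer bins; and the
noise is Gaussian rather than read-level Poisson (a ``poisson`` noise
model exists for realism checks).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GenomeGrid, make_grid
from .hic import PTC, ContactScoreSet
from .segmentation import Segment
from .track_matrix import BinnedTrackMatrix

__all__ = [
    "FixtureSpec",
    "default_fixture_spec",
    "no_signal_fixture_spec",
    "generate_tracks",
    "generate_contacts",
    "generate_genes",
    "planted_boundary_bins",
    "hub_recovery",
    "boundary_displacements",
    "write_fixture_dir",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic dataset.

    planted_segments are (chrom, start_bin, end_bin, mean_level) regions
    of elevated regional signal on the *structured* tracks; the
    remainder of the genome sits at ``baseline_mean``.  enhancer_regions
    are (chrom, start_bin, end_bin, density): a fraction ``density`` of
    their bins is jointly boosted on the mark tracks so the bins pass
    the joint Z >= 1 enhancer call.  hubs are sets of enhancer-region
    indices whose bin pairs receive contact scores centred on
    ``hub_score_mean`` instead of ``background_score_mean``.
    """

    chrom_sizes: dict[str, int]
    bin_size: int = 5000
    mark_tracks: tuple[str, ...] = ("H3K27ac", "ATAC")
    structured_tracks: tuple[str, ...] = ("H3K4me3", "CEBPA")
    baseline_mean: float = 4.0
    planted_segments: tuple[tuple[str, int, int, float], ...] = ()
    enhancer_regions: tuple[tuple[str, int, int, float], ...] = ()
    enhancer_boost: float = 80.0
    hubs: tuple[tuple[int, ...], ...] = ()
    hub_score_mean: float = 20.0
    background_score_mean: float = 0.0
    score_sd: float = 1.0
    noise_sd: float = 1.0
    noise_model: str = "gaussian"  # or "poisson"
    contacts_per_chrom: int = 12000
    contacts_per_hub_pair: int = 40
    contact_decay_bins: float = 150.0
    contact_max_gap_bins: int = 450
    seed: int = 0

    def __post_init__(self) -> None:
        for chrom, s, e, dens in self.enhancer_regions:
            if not (0.0 <= dens <= 1.0):
                raise ValueError(f"enhancer density must be in [0,1], got {dens}")
            if chrom not in self.chrom_sizes:
                raise ValueError(f"enhancer region on unknown chromosome {chrom}")
        seen: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e, _m in self.planted_segments:
            for s2, e2 in seen.get(chrom, []):
                if s < e2 and s2 < e:
                    raise ValueError(
                        f"planted segments overlap on {chrom}: [{s},{e}) vs [{s2},{e2})")
            seen.setdefault(chrom, []).append((s, e))
        for hub in self.hubs:
            for i in hub:
                if not (0 <= i < len(self.enhancer_regions)):
                    raise ValueError(f"hub references unknown enhancer region {i}")

    def grid(self) -> GenomeGrid:
        return make_grid(self.chrom_sizes, self.bin_size)

    @property
    def track_names(self) -> list[str]:
        return list(self.mark_tracks) + list(self.structured_tracks)


def default_fixture_spec(seed: int = 0) -> FixtureSpec:
    """Two 7.5-Mb chromosomes (1500 x 5-kb bins each), three planted hubs.

    Hubs hold two to three enhancer regions each; members sit within
    2 Mb of one another, distinct hubs are separated by > 2 Mb or lie on
    different chromosomes, so each must surface as its own condensate
    under the default distance cap.  The hub/background contact-score
    gap is 20 with unit score noise.
    """
    elevated = (
        ("chrA", 280, 360),
        ("chrA", 420, 480),
        ("chrA", 980, 1040),
        ("chrA", 1100, 1160),
        ("chrA", 1220, 1280),
        ("chrB", 380, 440),
        ("chrB", 500, 560),
    )
    return FixtureSpec(
        chrom_sizes={"chrA": 7_500_000, "chrB": 7_500_000},
        # enhancer regions coincide with the elevated segments: a
        # condensate-competent segment is enhancer-dense end to end (the
        # super-enhancer-like footprint), so a random equally sized
        # placement can only match its count by aligning almost exactly
        planted_segments=tuple((c, s, e, 8.0) for c, s, e in elevated),
        enhancer_regions=tuple((c, s, e, 0.9) for c, s, e in elevated),
        hubs=((0, 1), (2, 3, 4), (5, 6)),
        seed=seed,
    )


def no_signal_fixture_spec(seed: int = 0) -> FixtureSpec:
    """Same genome and enhancer layout, but no contact-score boost.

    Hub pairs score exactly like background, so no segment pair should
    pass any cutoff above the background score tail and the pipeline
    must call zero condensates there.
    """
    spec = default_fixture_spec(seed=seed)
    return FixtureSpec(**{**asdict(spec), "hub_score_mean": spec.background_score_mean})


# ---------------------------------------------------------------------------
# track generation
# ---------------------------------------------------------------------------

def enhancer_truth_bins(spec: FixtureSpec, grid: GenomeGrid,
                        rng: np.random.Generator) -> np.ndarray:
    """Sample the boosted-bin indicator for every enhancer region."""
    mask = np.zeros(grid.n_bins, dtype=bool)
    for chrom, s, e, dens in spec.enhancer_regions:
        off = grid.offset(chrom)
        sel = rng.random(e - s) < dens
        mask[off + s: off + e] = sel
    return mask


def generate_tracks(spec: FixtureSpec,
                    return_truth: bool = False):
    """Planted piecewise-constant tracks plus jointly boosted enhancer bins.

    Structured tracks carry the regional mean (baseline plus planted
    elevations); mark tracks are flat at baseline but receive the
    enhancer boost on density-sampled bins, jointly, so those bins — and
    only those — pass the joint Z >= 1 call after standardization.
    Values are truncated at zero.  Identical seeds give identical
    matrices.
    """
    grid = spec.grid()
    rng = np.random.default_rng(spec.seed)
    names = spec.track_names
    mean = np.full((grid.n_bins, len(names)), spec.baseline_mean, dtype=float)
    for chrom, s, e, level in spec.planted_segments:
        off = grid.offset(chrom)
        for j, name in enumerate(names):
            if name in spec.structured_tracks:
                mean[off + s: off + e, j] = level
    boosted = enhancer_truth_bins(spec, grid, rng)
    for j, name in enumerate(names):
        if name in spec.mark_tracks:
            mean[boosted, j] += spec.enhancer_boost

    if spec.noise_model == "gaussian":
        values = mean + rng.normal(0.0, spec.noise_sd, size=mean.shape)
    elif spec.noise_model == "poisson":
        values = rng.poisson(np.maximum(mean, 0.0)).astype(float)
    else:
        raise ValueError(f"unknown noise model {spec.noise_model!r}")
    values = np.maximum(values, 0.0)
    matrix = BinnedTrackMatrix(grid=grid, experiments=names, values=values,
                               normalization_tag="raw")
    if return_truth:
        return matrix, boosted
    return matrix


# ---------------------------------------------------------------------------
# contact generation
# ---------------------------------------------------------------------------

def _region_bins(spec: FixtureSpec, idx: int) -> tuple[str, np.ndarray]:
    chrom, s, e, _d = spec.enhancer_regions[idx]
    return chrom, np.arange(s, e)

def generate_contacts(spec: FixtureSpec, grid: GenomeGrid | None = None) -> ContactScoreSet:
    """Background contacts with distance decay plus boosted hub pairs.

    Background: per chromosome, ``contacts_per_chrom`` bin pairs with an
    exponentially distributed gap (scale ``contact_decay_bins``, capped
    at ``contact_max_gap_bins``) and scores ~ N(background_score_mean,
    score_sd).  Hub structure: every unordered pair of member regions of
    a hub — including a region with itself, so intra-segment entries are
    exercised — receives ``contacts_per_hub_pair`` bin pairs scored
    ~ N(hub_score_mean, score_sd).  Positions are bin midpoints.
    """
    grid = grid or spec.grid()
    rng = np.random.default_rng(spec.seed + 1)
    bs = grid.bin_size
    mid = bs // 2
    chroms, p1s, p2s, scores = [], [], [], []

    # bin -> hub membership map: background contacts landing with both ends
    # inside regions of one hub carry hub-level scores (in a normalized
    # track, contacts within an interacting hub score high throughout)
    hub_of = np.full(grid.n_bins, -1, dtype=int)
    for hi, hub in enumerate(spec.hubs):
        for ri in hub:
            chrom, bins = _region_bins(spec, ri)
            hub_of[grid.offset(chrom) + bins] = hi

    for chrom in grid.chroms:
        n = grid.n_bins_chrom(chrom)
        off = grid.offset(chrom)
        b1 = rng.integers(0, n, size=spec.contacts_per_chrom)
        gap = np.minimum(
            rng.exponential(spec.contact_decay_bins, size=spec.contacts_per_chrom),
            spec.contact_max_gap_bins).astype(int)
        b2 = np.minimum(b1 + gap, n - 1)
        sc = rng.normal(spec.background_score_mean, spec.score_sd,
                        size=spec.contacts_per_chrom)
        h1, h2 = hub_of[off + b1], hub_of[off + b2]
        in_hub = (h1 >= 0) & (h1 == h2)
        sc[in_hub] += spec.hub_score_mean - spec.background_score_mean
        chroms.append(np.full(b1.size, chrom, dtype=object))
        p1s.append(b1 * bs + mid)
        p2s.append(b2 * bs + mid)
        scores.append(sc)

    for hub in spec.hubs:
        members = sorted(hub)
        for ii, i in enumerate(members):
            for j in members[ii:]:
                chrom_i, bins_i = _region_bins(spec, i)
                chrom_j, bins_j = _region_bins(spec, j)
                if chrom_i != chrom_j:
                    raise ValueError("hub members must share a chromosome")
                b1 = rng.choice(bins_i, size=spec.contacts_per_hub_pair)
                b2 = rng.choice(bins_j, size=spec.contacts_per_hub_pair)
                sc = rng.normal(spec.hub_score_mean, spec.score_sd,
                                size=spec.contacts_per_hub_pair)
                chroms.append(np.full(b1.size, chrom_i, dtype=object))
                p1s.append(b1 * bs + mid)
                p2s.append(b2 * bs + mid)
                scores.append(sc)

    df = pd.DataFrame({
        "chrom1": np.concatenate(chroms),
        "pos1": np.concatenate(p1s).astype(np.int64),
        "chrom2": np.concatenate(chroms),
        "pos2": np.concatenate(p2s).astype(np.int64),
        "score": np.concatenate(scores),
    })
    return ContactScoreSet(df, source_tag="external_normalized")


# ---------------------------------------------------------------------------
# genes + expression
# ---------------------------------------------------------------------------

def generate_genes(spec: FixtureSpec, conditions: list[str] | None = None,
                   n_background_genes: int = 6) -> pd.DataFrame:
    """One expressed gene per enhancer region plus silent background genes.

    Returns a frame with gene_id/chrom/start/end/tss and one tpm_<cond>
    column per condition (default a single condition "cond0").
    """
    conditions = conditions or ["cond0"]
    grid = spec.grid()
    rng = np.random.default_rng(spec.seed + 2)
    bs = spec.bin_size
    rows = []
    for i, (chrom, s, e, _d) in enumerate(spec.enhancer_regions):
        start, end = s * bs, e * bs
        row = {"gene_id": f"gene_region{i}", "chrom": chrom, "start": start,
               "end": end, "tss": (start + end) // 2}
        for c in conditions:
            row[f"tpm_{c}"] = float(np.round(rng.uniform(5, 50), 2))
        rows.append(row)
    for k in range(n_background_genes):
        chrom = grid.chroms[k % len(grid.chroms)]
        start = int(rng.integers(0, grid.chrom_sizes[chrom] - 50_000))
        row = {"gene_id": f"gene_bg{k}", "chrom": chrom, "start": start,
               "end": start + 30_000, "tss": start}
        for c in conditions:
            row[f"tpm_{c}"] = 0.0
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth + evaluation
# ---------------------------------------------------------------------------

def planted_boundary_bins(spec: FixtureSpec) -> dict[str, list[int]]:
    """Chromosome-local bin indices of the planted mean changepoints."""
    out: dict[str, list[int]] = {c: [] for c in spec.chrom_sizes}
    grid = spec.grid()
    for chrom, s, e, _m in spec.planted_segments:
        n = grid.n_bins_chrom(chrom)
        for b in (s, e):
            if 0 < b < n:
                out[chrom].append(b)
    return {c: sorted(set(v)) for c, v in out.items()}


def boundary_displacements(segments: list[Segment], spec: FixtureSpec) -> pd.DataFrame:
    """Distance (bins) from each planted boundary to the nearest detected one."""
    detected: dict[str, np.ndarray] = {}
    for seg in segments:
        detected.setdefault(seg.chrom, [])
    for seg in segments:
        if seg.start_bin > 0:
            detected[seg.chrom].append(seg.start_bin)
    rows = []
    for chrom, truths in planted_boundary_bins(spec).items():
        det = np.array(sorted(set(detected.get(chrom, []))))
        for t in truths:
            disp = int(np.min(np.abs(det - t))) if det.size else np.inf
            rows.append({"chrom": chrom, "truth_bin": t, "displacement_bins": disp})
    return pd.DataFrame(rows)


def hub_recovery(ptcs: list[PTC], spec: FixtureSpec,
                 segments: list[Segment]) -> pd.DataFrame:
    """Region-level Jaccard between planted hubs and called condensates.

    Each PTC is mapped to the set of planted enhancer regions its member
    segments overlap; a hub is perfectly recovered when exactly one PTC
    maps to exactly the hub's region set (Jaccard 1) and no other PTC
    touches it.
    """
    seg_by_id = {s.id: s for s in segments}
    regions = [(chrom, s * spec.bin_size, e * spec.bin_size)
               for chrom, s, e, _d in spec.enhancer_regions]

    def ptc_regions(p: PTC) -> frozenset[int]:
        hit = set()
        for sid in p.member_segment_ids:
            seg = seg_by_id[sid]
            for ri, (chrom, rs, re_) in enumerate(regions):
                if seg.chrom == chrom and seg.start < re_ and rs < seg.end:
                    hit.add(ri)
        return frozenset(hit)

    mapped = [(p.ptc_id, ptc_regions(p)) for p in ptcs]
    rows = []
    for hi, hub in enumerate(spec.hubs):
        hubset = frozenset(hub)
        touching = [(pid, rs) for pid, rs in mapped if rs & hubset]
        jac = max((len(rs & hubset) / len(rs | hubset) for _pid, rs in touching),
                  default=0.0)
        rows.append({
            "hub": hi,
            "n_ptcs_touching": len(touching),
            "best_jaccard": jac,
            "recovered_exactly": len(touching) == 1 and touching[0][1] == hubset,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk fixture directory (for the CLI)
# ---------------------------------------------------------------------------

def write_fixture_dir(spec: FixtureSpec, outdir: str | Path,
                      conditions: list[str] | None = None) -> Path:
    """Materialize a fixture as plain-text inputs the CLI can consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = spec.grid()
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom, size in spec.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    matrix = generate_tracks(spec)
    bin_df = grid.bin_frame()
    lengths = grid.bin_lengths()
    for j, name in enumerate(matrix.experiments):
        bg = bin_df.copy()
        bg["value"] = matrix.values[:, j] / lengths  # per-bp rate: binning recovers mass
        bg.to_csv(outdir / f"{name}.bedGraph", sep="\t", header=False, index=False)
    contacts = generate_contacts(spec, grid)
    contacts.records.to_csv(outdir / "contacts.tsv", sep="\t", index=False)
    genes = generate_genes(spec, conditions)
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    truth = {
        "boundaries": planted_boundary_bins(spec),
        "hubs": [list(h) for h in spec.hubs],
        "enhancer_regions": [list(r) for r in spec.enhancer_regions],
        "seed": spec.seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return outdir
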