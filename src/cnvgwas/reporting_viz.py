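"""Manhattan and region-distribution plots, plus catalog highlighting.

Every figure is written together with a JSON *sidecar* (``<image>.json``)
carrying the per-point metadata a GUI would show on click: the Bonferroni
line position and the number of tests behind it, per-point coordinates and
flags, and the per-chromosome color assignment.  Rendering itself is only
smoke-checked downstream; the sidecar is the machine-readable contract.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .errors import ConfigError, ValidationError
from .io_formats import CatalogRegion, CHROMOSOME_ORDER, chromosome_sort_key

__all__ = ["PlotSpec", "manhattan_plot", "region_distribution_plot", "annotate_catalog"]

#: Display ceiling for −log10(p); p-values of exactly 0 are clipped here and
#: the sidecar records the clipping.
LOG10P_CEILING = 320.0

_DEFAULT_COLORS = ("#4C72B0", "#DD8452", "#55A868", "#C44E52",
                   "#8172B3", "#937860", "#DA8BC3", "#8C8C8C")


@dataclass
class PlotSpec:
    """Where and how to render a figure."""

    path: Path
    image_format: str = "png"
    width_px: int = 1200
    height_px: int = 500
    dpi: int = 100
    alpha: float = 0.05
    colors: tuple = _DEFAULT_COLORS

    def __post_init__(self):
        self.path = Path(self.path)
        if self.image_format.lower() not in ("png", "jpeg", "jpg"):
            raise ConfigError(f"image format must be PNG or JPEG, got {self.image_format!r}")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ConfigError("plot dimensions must be positive")

    @property
    def figsize(self):
        return (self.width_px / self.dpi, self.height_px / self.dpi)

    @property
    def sidecar_path(self) -> Path:
        return Path(str(self.path) + ".json")


def _chrom_layout(chromosomes, spans):
    """Cumulative x-offsets: chromosomes concatenated in natural order with a
    fixed gap of 2% of the total plotted span between them."""
    lengths = {c: max(end for _, end in spans[c]) for c in chromosomes}
    total = sum(lengths.values())
    gap = max(1.0, 0.02 * total)
    offsets, cursor = {}, 0.0
    for c in chromosomes:
        offsets[c] = cursor
        cursor += lengths[c] + gap
    return offsets, gap


def manhattan_plot(results, spec: PlotSpec, alpha: Optional[float] = None,
                   m_tested: Optional[int] = None) -> Path:
    """−log10(p) against cumulative genomic position, with the Bonferroni line.

    The horizontal significance line sits at ``−log10(alpha / M)`` where ``M``
    defaults to the number of plotted results; pass ``m_tested`` when some
    regions were skipped so the line reflects the tests actually performed.
    """
    results = list(results)
    if not results:
        raise ValidationError("manhattan_plot needs at least one result")
    alpha = spec.alpha if alpha is None else alpha
    m = m_tested if m_tested is not None else len(results)
    threshold = alpha / m
    line_y = -math.log10(threshold)

    chroms = sorted({r.chromosome for r in results}, key=chromosome_sort_key)
    spans = {c: [(r.start_pos, r.end_pos) for r in results if r.chromosome == c]
             for c in chroms}
    offsets, _ = _chrom_layout(chroms, spans)
    color_of = {c: spec.colors[i % len(spec.colors)] for i, c in enumerate(chroms)}

    points = []
    clipped = False
    for r in results:
        midpoint = (r.start_pos + r.end_pos) / 2.0
        if r.p_value <= 0.0:
            y = LOG10P_CEILING
            clipped = True
        else:
            y = min(-math.log10(r.p_value), LOG10P_CEILING)
            clipped = clipped or y >= LOG10P_CEILING
        points.append(
            {
                "region_id": r.region_id,
                "chromosome": r.chromosome,
                "start": r.start_pos,
                "end": r.end_pos,
                "x": offsets[r.chromosome] + midpoint,
                "y": y,
                "p_value": r.p_value,
                "significant": bool(r.significant),
                "catalog_hit": bool(getattr(r, "catalog_hit", False)),
                "color": color_of[r.chromosome],
            }
        )

    fig, ax = plt.subplots(figsize=spec.figsize, dpi=spec.dpi)
    for c in chroms:
        xs = [p["x"] for p in points if p["chromosome"] == c]
        ys = [p["y"] for p in points if p["chromosome"] == c]
        ax.scatter(xs, ys, s=14, color=color_of[c], label=c, zorder=2)
    hits = [p for p in points if p["catalog_hit"]]
    if hits:
        ax.scatter([p["x"] for p in hits], [p["y"] for p in hits],
                   s=60, facecolors="none", edgecolors="#E6C229", linewidths=1.5,
                   zorder=3, label="known association")
    sig = [p for p in points if p["significant"]]
    if sig:
        ax.scatter([p["x"] for p in sig], [p["y"] for p in sig],
                   s=26, color="#C2202A", zorder=4)
    ax.axhline(line_y, color="firebrick", linestyle="--", linewidth=1,
               label=f"Bonferroni (α={alpha:g}, M={m})")
    ax.set_xticks([offsets[c] + max(e for _, e in spans[c]) / 2 for c in chroms])
    ax.set_xticklabels(chroms)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    title = "CNV region associations"
    if clipped:
        title += f"  (p-values clipped at 1e-{LOG10P_CEILING:.0f})"
    ax.set_title(title)
    ax.legend(loc="upper right", fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(spec.path, format="jpeg" if spec.image_format.lower() == "jpg"
                else spec.image_format.lower())
    plt.close(fig)

    sidecar = {
        "plot": "manhattan",
        "alpha": alpha,
        "m_tested": m,
        "bonferroni_threshold": threshold,
        "line_y": line_y,
        "clip_ceiling": LOG10P_CEILING,
        "clipped": clipped,
        "chromosome_colors": color_of,
        "n_points": len(points),
        "points": points,
    }
    spec.sidecar_path.write_text(json.dumps(sidecar, indent=1), encoding="utf-8")
    return spec.path


def region_distribution_plot(regions, spec: PlotSpec,
                             chromosomes: Optional[Sequence[str]] = None) -> Path:
    """One horizontal track per chromosome with a glyph at each region's span.

    Tracks for chromosomes without regions are still drawn (empty), so the
    genome-wide layout is stable across runs; by default all human
    chromosomes (1..22, X, Y) get a track.
    """
    regions = list(regions)
    if not regions:
        raise ValidationError("region_distribution_plot needs at least one region")
    if chromosomes is None:
        present = {r.chromosome for r in regions}
        chromosomes = [c for c in CHROMOSOME_ORDER] + sorted(
            present - set(CHROMOSOME_ORDER), key=chromosome_sort_key
        )
    track_of = {c: i for i, c in enumerate(chromosomes)}
    unknown = {r.chromosome for r in regions} - set(chromosomes)
    if unknown:
        raise ValidationError(f"regions on chromosomes outside the track list: {sorted(unknown)}")

    max_pos = max(r.end_pos for r in regions)
    min_width = 0.004 * max_pos  # keep kb-scale regions visible at genome scale
    fig, ax = plt.subplots(figsize=spec.figsize, dpi=spec.dpi)
    glyphs = []
    for c in chromosomes:
        ax.axhline(track_of[c], color="0.85", linewidth=0.8, zorder=1)
    for r in regions:
        y = track_of[r.chromosome]
        width = max(r.end_pos - r.start_pos + 1, min_width)
        ax.broken_barh([(r.start_pos, width)], (y - 0.35, 0.7),
                       facecolors=spec.colors[track_of[r.chromosome] % len(spec.colors)],
                       zorder=2)
        glyphs.append({"region_id": r.region_id, "chromosome": r.chromosome,
                       "start": r.start_pos, "end": r.end_pos,
                       "frequency": r.frequency, "track": y})
    ax.set_yticks(range(len(chromosomes)))
    ax.set_yticklabels(chromosomes, fontsize=7)
    ax.invert_yaxis()
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("chromosome")
    ax.set_title("Distribution of detected CNV regions")
    fig.tight_layout()
    fig.savefig(spec.path, format="jpeg" if spec.image_format.lower() == "jpg"
                else spec.image_format.lower())
    plt.close(fig)

    per_chrom = {c: 0 for c in chromosomes}
    for g in glyphs:
        per_chrom[g["chromosome"]] += 1
    spec.sidecar_path.write_text(
        json.dumps(
            {
                "plot": "region_distribution",
                "n_regions": len(regions),
                "n_glyphs": len(glyphs),
                "tracks": list(chromosomes),
                "per_chromosome": per_chrom,
                "glyphs": glyphs,
            },
            indent=1,
        ),
        encoding="utf-8",
    )
    return spec.path


def annotate_catalog(results, catalog: Sequence[CatalogRegion],
                     trait: Optional[str] = None):
    """Flag results whose span overlaps a known-association region (≥1 bp).

    Pure annotation: a new result list is returned with ``catalog_hit`` set;
    betas, p-values and ordering are untouched.  With ``trait`` given, only
    catalog entries for that trait (case-insensitive) count.
    """
    entries = [
        e for e in catalog
        if trait is None or e.trait.strip().lower() == trait.strip().lower()
    ]
    annotated = []
    for r in results:
        hit = any(
            e.chromosome == r.chromosome
            and min(e.end_pos, r.end_pos) - max(e.start_pos, r.start_pos) >= 0
            for e in entries
        )
        annotated.append(replace(r, catalog_hit=hit))
    return annotated
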