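"""Frame-by-frame analysis pipeline and result output.

Streams frames (bounded memory: one frame resident at a time),
accumulates per-frame time series and time-averaged histograms, and
writes the deterministic output file set: TSV histograms and time
series, a JSON summary, and optional PDB / edge-list exports of the
structural heterogeneities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from . import __version__
from .core import Frame
from .energetics import DEFAULT_PARAMS, PairEnergyTable, TIP4P2005Params
from .hbonds import HBondCriteria, classify_pairs
from .heterogeneity import (
    DEFAULT_SIZE_MIN,
    TABLE_SIZES,
    find_heterogeneities,
    short_bond_degree_stats,
)
from .io import (
    write_edge_list_tsv,
    write_histogram_tsv,
    write_json_summary,
    write_series_tsv,
    write_sh_pdb,
)
from .network import Histogram, _anchored_edges, build_bond_network
from .timeseries import AveragingWindow, default_window, window_summary

__all__ = ["AnalysisConfig", "AnalysisResults", "analyze_frames", "write_outputs"]


class _HistAccumulator:
    """Per-frame count accumulator for time-averaged histograms."""

    def __init__(self, lo: float, hi: float, bin_width: float) -> None:
        self.edges = _anchored_edges(lo, hi, bin_width)
        self.acc = np.zeros(len(self.edges) - 1)
        self.n_frames = 0

    def add(self, samples: np.ndarray) -> None:
        counts, _ = np.histogram(samples, bins=self.edges)
        if len(samples) and np.any(samples == self.edges[-1]):
            counts[-1] -= int(np.sum(samples == self.edges[-1]))
        self.acc += counts
        self.n_frames += 1

    def result(self) -> Histogram:
        n = max(self.n_frames, 1)
        return Histogram(self.edges, self.acc / n, "raw")


@dataclass(frozen=True)
class AnalysisConfig:
    criteria: HBondCriteria = field(default_factory=HBondCriteria)
    params: TIP4P2005Params = DEFAULT_PARAMS
    size_min: int = DEFAULT_SIZE_MIN
    distance_bin: float = 0.01
    angle_bin: float = 1.0
    energy_bin: float = 0.1
    compute_energies: bool = True
    max_degree_bucket: int = 5
    table_sizes: tuple[int, ...] = TABLE_SIZES


@dataclass
class AnalysisResults:
    """Accumulated per-frame series and time-averaged histograms."""

    config: AnalysisConfig
    n_mol: int
    times: np.ndarray
    # bond network series
    pairs_per_molecule: np.ndarray
    coordination_mean: np.ndarray  # n(R) = 2 N_OO / N_mol
    coordination_fractions: np.ndarray  # (n_frames, k_max+1)
    # H-bond series
    hbonds_per_molecule: np.ndarray
    hbonds_per_pair: np.ndarray
    short_per_molecule: np.ndarray
    hbond_degree_fractions: np.ndarray  # (n_frames, max_degree_bucket+1)
    short_rejected_by_angle: np.ndarray
    # SH series
    sh_fraction: np.ndarray
    sh_size_counts: list[dict[int, int]]
    sh_bonds_per_molecule: np.ndarray
    sh_bonds_per_sh_molecule: np.ndarray
    sh_degree_fractions: np.ndarray  # (n_frames, 5) over SH members, degrees 1..4+
    u_ave_short: np.ndarray  # NaN where no SH short bond exists
    # histograms
    distance_hist: Histogram
    hbond_length_hist: Histogram
    angle_hist: Histogram
    energy_hist_hbonded: Histogram | None
    energy_hist_nonbonded: Histogram | None
    energy_hist_short: Histogram | None
    # last-frame SH snapshot for optional exports
    last_frame: Frame | None
    last_components: list[np.ndarray]
    sh_edge_rows: list[tuple[float, int, int, float, float]]

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def sh_size_table(self) -> dict[int, float]:
        out = {int(s): 0.0 for s in self.config.table_sizes}
        for counts in self.sh_size_counts:
            for s in out:
                out[s] += counts.get(s, 0)
        return {s: v / max(len(self.sh_size_counts), 1) for s, v in out.items()}


def analyze_frames(frames: Iterable[Frame], config: AnalysisConfig = AnalysisConfig()) -> AnalysisResults:
    """Run the full per-frame pipeline over a frame stream."""
    crit = config.criteria
    dist_acc = _HistAccumulator(2.2, crit.r_max, config.distance_bin)
    hblen_acc = _HistAccumulator(2.2, crit.r_max, config.distance_bin)
    ang_acc = _HistAccumulator(0.0, 180.0, config.angle_bin)
    e_acc = {
        name: _HistAccumulator(-10.0, 10.0, config.energy_bin)
        for name in ("hbonded", "nonbonded", "short_hbonded")
    }

    times: list[float] = []
    ppm, nmean, hpm, hpp, spm, rej = [], [], [], [], [], []
    coord_rows: list[np.ndarray] = []
    deg_rows: list[np.ndarray] = []
    shfrac, shsizes, shbpm, shbpsm = [], [], [], []
    shdeg_rows: list[np.ndarray] = []
    uave: list[float] = []
    n_mol = None
    last_frame = None
    last_components: list[np.ndarray] = []
    sh_edge_rows: list[tuple[float, int, int, float, float]] = []

    for frame in frames:
        if n_mol is None:
            n_mol = frame.n_mol
        elif frame.n_mol != n_mol:
            raise ValueError(
                f"frame at t={frame.time} fs has {frame.n_mol} molecules, expected {n_mol}"
            )
        net = build_bond_network(frame, crit.r_max)
        cn = classify_pairs(frame, net, crit)
        decomp = find_heterogeneities(cn, config.size_min)
        sh_deg = short_bond_degree_stats(cn, decomp)

        times.append(frame.time)
        ppm.append(net.n_pairs / n_mol)
        nmean.append(2.0 * net.n_pairs / n_mol)
        deg = net.degrees()
        coord_rows.append(np.bincount(deg, minlength=1) / n_mol)
        hpm.append(cn.n_hbonds / n_mol)
        hpp.append(cn.n_hbonds / net.n_pairs if net.n_pairs else 0.0)
        spm.append(cn.n_short / n_mol)
        rej.append(cn.n_short_rejected_by_angle)
        hdeg = cn.hbond_degrees()
        frac = np.zeros(config.max_degree_bucket + 1)
        for k, c in enumerate(np.bincount(hdeg, minlength=1)):
            frac[min(k, config.max_degree_bucket)] += c
        deg_rows.append(frac / n_mol)

        shfrac.append(decomp.fraction_in_sh)
        shsizes.append(decomp.size_counts())
        shbpm.append(sh_deg.mean_bonds_per_molecule)
        shbpsm.append(sh_deg.mean_bonds_per_sh_molecule)
        shdeg_rows.append(sh_deg.degree_fractions(4))

        dist_acc.add(net.d_OO)
        hblen_acc.add(net.d_OO[cn.hbond_mask])
        ang_acc.add(cn.angle_min)

        if config.compute_energies:
            table = PairEnergyTable.from_classified(frame, cn, config.params)
            e_acc["hbonded"].add(table.U[table.labels >= 1])
            e_acc["nonbonded"].add(table.U[table.labels < 1])
            e_acc["short_hbonded"].add(table.U[table.labels == 2])
            members = decomp.member_index_set()
            sh_short = [
                (k, i, j)
                for k, (i, j) in enumerate(table.pairs)
                if table.labels[k] == 2 and i in members and j in members
            ]
            uave.append(
                float(np.mean([table.U[k] for k, _, _ in sh_short])) if sh_short else np.nan
            )
            for k, i, j in sh_short:
                sh_edge_rows.append(
                    (
                        frame.time,
                        int(net.molecule_ids[i]),
                        int(net.molecule_ids[j]),
                        float(net.d_OO[k]),
                        float(table.U[k]),
                    )
                )
        else:
            uave.append(np.nan)
        last_frame = frame
        last_components = decomp.components

    if n_mol is None:
        raise ValueError("no frames to analyze")

    def _pad(rows: list[np.ndarray]) -> np.ndarray:
        width = max(len(r) for r in rows)
        return np.array([np.pad(r, (0, width - len(r))) for r in rows])

    return AnalysisResults(
        config=config,
        n_mol=n_mol,
        times=np.array(times),
        pairs_per_molecule=np.array(ppm),
        coordination_mean=np.array(nmean),
        coordination_fractions=_pad(coord_rows),
        hbonds_per_molecule=np.array(hpm),
        hbonds_per_pair=np.array(hpp),
        short_per_molecule=np.array(spm),
        hbond_degree_fractions=np.array(deg_rows),
        short_rejected_by_angle=np.array(rej),
        sh_fraction=np.array(shfrac),
        sh_size_counts=shsizes,
        sh_bonds_per_molecule=np.array(shbpm),
        sh_bonds_per_sh_molecule=np.array(shbpsm),
        sh_degree_fractions=np.array(shdeg_rows),
        u_ave_short=np.array(uave),
        distance_hist=dist_acc.result(),
        hbond_length_hist=hblen_acc.result(),
        angle_hist=ang_acc.result(),
        energy_hist_hbonded=e_acc["hbonded"].result() if config.compute_energies else None,
        energy_hist_nonbonded=e_acc["nonbonded"].result() if config.compute_energies else None,
        energy_hist_short=e_acc["short_hbonded"].result() if config.compute_energies else None,
        last_frame=last_frame,
        last_components=last_components,
        sh_edge_rows=sh_edge_rows,
    )


def _summaries(results: AnalysisResults, window: AveragingWindow) -> dict:
    t = results.times

    def summ(values: np.ndarray) -> dict:
        mask = ~np.isnan(values)
        if not mask.any():
            return {"mean": None, "std": None, "n_frames": 0}
        s = window_summary(t[mask], values[mask], window)
        return {"mean": s.mean, "std": s.std, "n_frames": s.n_frames}

    in_window = (t >= window.t_start) & (t <= window.t_end)
    coord_mean_frac = results.coordination_fractions[in_window].mean(axis=0)
    hdeg_mean_frac = results.hbond_degree_fractions[in_window].mean(axis=0)
    shdeg_mean_frac = results.sh_degree_fractions[in_window].mean(axis=0)
    return {
        "window_fs": [window.t_start, window.t_end],
        "n_mol": results.n_mol,
        "n_frames": results.n_frames,
        "pairs_per_molecule": summ(results.pairs_per_molecule),
        "coordination_mean": summ(results.coordination_mean),
        "coordination_fractions": coord_mean_frac.tolist(),
        "hbonds_per_molecule": summ(results.hbonds_per_molecule),
        "hbonds_per_pair": summ(results.hbonds_per_pair),
        "short_hbonds_per_molecule": summ(results.short_per_molecule),
        "hbond_degree_fractions": hdeg_mean_frac.tolist(),
        "short_rejected_by_angle": summ(results.short_rejected_by_angle.astype(float)),
        "sh_molecule_fraction": summ(results.sh_fraction),
        "sh_bonds_per_molecule": summ(results.sh_bonds_per_molecule),
        "sh_bonds_per_sh_molecule": summ(results.sh_bonds_per_sh_molecule),
        "sh_degree_fractions": shdeg_mean_frac.tolist(),
        "sh_size_table": {str(k): v for k, v in results.sh_size_table().items()},
        "u_ave_short_in_sh": summ(results.u_ave_short),
    }


def write_outputs(
    results: AnalysisResults,
    outdir: str | Path,
    window: AveragingWindow | None = None,
    metadata: Mapping[str, object] | None = None,
    export_pdb: bool = False,
    export_edges: bool = False,
) -> dict:
    """Write the deterministic output file set; returns the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    crit = results.config.criteria
    meta = {
        "tool": f"hbnet {__version__}",
        "r_max_A": crit.r_max,
        "angle_max_deg": crit.angle_max,
        "r_short_A": crit.r_short,
        "size_min": results.config.size_min,
        **(metadata or {}),
    }
    if window is None:
        window = default_window(float(results.times.min()), float(results.times.max()))
    meta["window_fs"] = f"{window.t_start}..{window.t_end}"

    write_histogram_tsv(outdir / "distance_hist.tsv", results.distance_hist, meta)
    write_histogram_tsv(outdir / "hbond_length_hist.tsv", results.hbond_length_hist, meta)
    write_histogram_tsv(outdir / "angle_hist.tsv", results.angle_hist, meta)
    if results.energy_hist_hbonded is not None:
        write_histogram_tsv(outdir / "energy_hist_hbonded.tsv", results.energy_hist_hbonded, meta)
        write_histogram_tsv(
            outdir / "energy_hist_nonbonded.tsv", results.energy_hist_nonbonded, meta
        )
        write_histogram_tsv(outdir / "energy_hist_short.tsv", results.energy_hist_short, meta)

    write_series_tsv(
        outdir / "network_series.tsv",
        results.times,
        {
            "pairs_per_molecule": results.pairs_per_molecule,
            "coordination_mean": results.coordination_mean,
        },
        meta,
    )
    write_series_tsv(
        outdir / "hbond_series.tsv",
        results.times,
        {
            "hbonds_per_molecule": results.hbonds_per_molecule,
            "hbonds_per_pair": results.hbonds_per_pair,
            "short_per_molecule": results.short_per_molecule,
        },
        meta,
    )
    write_series_tsv(
        outdir / "sh_series.tsv",
        results.times,
        {
            "sh_fraction": results.sh_fraction,
            "sh_bonds_per_molecule": results.sh_bonds_per_molecule,
            "u_ave_short": results.u_ave_short,
        },
        meta,
    )
    summary = _summaries(results, window)
    summary["metadata"] = {k: str(v) for k, v in meta.items()}
    write_json_summary(outdir / "summary.json", summary)

    if export_pdb and results.last_frame is not None:
        write_sh_pdb(outdir / "sh_last_frame.pdb", results.last_frame, results.last_components)
    if export_edges:
        write_edge_list_tsv(outdir / "sh_edges.tsv", results.sh_edge_rows, meta)
    return summary
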