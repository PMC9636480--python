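"""All-pairwise fusion x control comparison design.

Every fusion replicate is compared against every Dam-only control
replicate; each pair is named ``<exp>_vs_<ctrl>`` and owns one output
directory.  The same machinery runs control-vs-control negative designs,
where comparisons of a sample against itself are excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

from .counts import FragmentCounts
from .peaks import PeakCallParams, call_broad_peaks, write_broadpeak
from .tracks import RatioParams, ratio_track, write_bedgraph

__all__ = ["ComparisonGrid", "build_grid", "run_grid"]


@dataclass(frozen=True)
class ComparisonGrid:
    exp_ids: Tuple[str, ...]
    ctrl_ids: Tuple[str, ...]
    pairs: Tuple[Tuple[str, str], ...]
    exclude_self: bool = False

    @property
    def names(self) -> List[str]:
        return [f"{e}_vs_{c}" for e, c in self.pairs]


def build_grid(
    exp_ids: Sequence[str], ctrl_ids: Sequence[str], exclude_self: bool = False
) -> ComparisonGrid:
    """Cartesian product of experiments x controls, exp-major order.

    ``exclude_self`` drops pairs whose two IDs are identical (used when a
    sample list is compared against itself for negative controls).
    """
    if not exp_ids or not ctrl_ids:
        raise ValueError("need at least one experimental and one control ID")
    if len(set(exp_ids)) != len(exp_ids):
        raise ValueError("duplicate experimental IDs")
    if len(set(ctrl_ids)) != len(ctrl_ids):
        raise ValueError("duplicate control IDs")
    pairs = tuple(
        (e, c) for e in exp_ids for c in ctrl_ids if not (exclude_self and e == c)
    )
    return ComparisonGrid(
        exp_ids=tuple(exp_ids), ctrl_ids=tuple(ctrl_ids), pairs=pairs, exclude_self=exclude_self
    )


def run_grid(
    grid: ComparisonGrid,
    counts_by_id: Dict[str, FragmentCounts],
    output_root: Path,
    ratio_params: RatioParams = RatioParams(),
    peak_params: PeakCallParams = PeakCallParams(),
    call_peaks: bool = True,
    log_extra: Dict[str, object] | None = None,
) -> Dict[str, Dict[str, object]]:
    """Execute every pairwise comparison, one directory per pair.

    Each ``<exp>_vs_<ctrl>`` directory receives the ratio bedgraph (and
    the broadPeak file when ``call_peaks``); a JSON run log at the root
    records all parameters.  Missing sample IDs abort before any output
    is written; re-running overwrites deterministically.
    """
    missing = sorted(
        {i for pair in grid.pairs for i in pair if i not in counts_by_id}
    )
    if missing:
        raise ValueError(f"missing counts for sample IDs: {missing}")
    output_root = Path(output_root)
    output_root.mkdir(parents=True, exist_ok=True)
    results: Dict[str, Dict[str, object]] = {}
    for (exp, ctrl), name in zip(grid.pairs, grid.names):
        pair_dir = output_root / name
        pair_dir.mkdir(exist_ok=True)
        track = ratio_track(counts_by_id[exp], counts_by_id[ctrl], ratio_params, label=name)
        write_bedgraph(track, pair_dir / f"{name}.ratio.bedgraph")
        entry: Dict[str, object] = {"exp": exp, "ctrl": ctrl, "dir": str(pair_dir)}
        if call_peaks:
            peaks = call_broad_peaks(
                counts_by_id[exp], counts_by_id[ctrl], peak_params, name_prefix=name
            )
            write_broadpeak(peaks, pair_dir / f"{name}.broadPeak")
            entry["n_peaks"] = len(peaks)
        results[name] = entry
    log = {
        "pairs": grid.names,
        "exp_ids": list(grid.exp_ids),
        "ctrl_ids": list(grid.ctrl_ids),
        "exclude_self": grid.exclude_self,
        "ratio_pseudocount": ratio_params.pseudocount,
        "significant_q": peak_params.significant_q,
        "linking_q": peak_params.linking_q,
        "background_windows": list(peak_params.background_windows),
        **(log_extra or {}),
    }
    (output_root / "run_grid.log.json").write_text(json.dumps(log, indent=2) + "\n")
    return results
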