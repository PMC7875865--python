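"""State-count selection: scan a range of model orders, repair log-likelihood
discontinuities with fresh seeds, pick the minimum-BIC model.

One scan is run per expertise group per image, on the pooled scanpaths of that
group. Because an HMM with N states nests every (N-1)-state model, the best
attainable log-likelihood must be non-decreasing in N; a drop signals a local
optimum, which is repaired by re-running EM from alternative random starts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateModelError, InfeasibleError, ScanError
from .hmm import FitResult, baum_welch, bic

log = logging.getLogger(__name__)

DEFAULT_N_MIN = 2
DEFAULT_N_MAX = 14
DEFAULT_RESTARTS = 3
DEFAULT_EXTRA_RESTARTS = 5
_MAX_REPAIR_ROUNDS = 4


def derive_seed(base_seed: int, *parts: int) -> int:
    """Deterministic child seed from a base seed and integer context (N, attempt...)."""
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=tuple(int(p) for p in parts))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class ScanEntry:
    n_states: int
    fit: FitResult
    bic: float
    seeds_tried: list[int]


@dataclass
class ModelScan:
    """Fits and BIC values across a state range for one group x image."""

    group: str
    image_id: str
    entries: dict[int, ScanEntry] = field(default_factory=dict)
    discontinuities: list[int] = field(default_factory=list)

    @property
    def n_range(self) -> list[int]:
        return sorted(self.entries)

    @property
    def selected_n(self) -> int:
        """State count with minimal BIC; ties go to the smaller model."""
        return min(self.n_range, key=lambda n: (self.entries[n].bic, n))

    def loglik(self, n: int) -> float:
        return self.entries[n].fit.log_likelihood

    def to_frame(self) -> pd.DataFrame:
        sel = self.selected_n
        rows = [
            {
                "group": self.group,
                "image_id": self.image_id,
                "n_states": n,
                "log_likelihood": e.fit.log_likelihood,
                "bic": e.bic,
                "selected": int(n == sel),
                "seeds_tried": ";".join(str(s) for s in e.seeds_tried),
            }
            for n, e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)


def _attempt(sequences, n, seed, attempt_idx, **fit_kwargs) -> FitResult | None:
    """One seeded EM attempt; attempt 0 uses k-means init, restarts use random."""
    strategy = "kmeans" if attempt_idx == 0 else "random"
    try:
        return baum_welch(sequences, n, seed=seed, strategy=strategy, **fit_kwargs)
    except (DegenerateModelError, InfeasibleError) as exc:
        log.debug("attempt N=%d seed=%d failed: %s", n, seed, exc)
        return None


def scan_state_range(
    sequences,
    n_min: int = DEFAULT_N_MIN,
    n_max: int = DEFAULT_N_MAX,
    restarts: int = DEFAULT_RESTARTS,
    base_seed: int = 0,
    group: str = "",
    image_id: str = "",
    **fit_kwargs,
) -> ModelScan:
    """Fit every state count in [n_min, n_max], keeping the best of ``restarts``
    seeded attempts per N. Fully reproducible from ``base_seed``."""
    if n_min < 1 or n_max < n_min:
        raise ScanError(f"invalid state range [{n_min}, {n_max}]")
    scan = ModelScan(group=group, image_id=image_id)
    for n in range(n_min, n_max + 1):
        best: FitResult | None = None
        seeds: list[int] = []
        for a in range(restarts):
            seed = derive_seed(base_seed, n, a)
            seeds.append(seed)
            fit = _attempt(sequences, n, seed, a, **fit_kwargs)
            if fit is not None and (best is None or fit.log_likelihood > best.log_likelihood):
                best = fit
        if best is None:
            raise ScanError(f"all {restarts} restarts degenerate for N={n}")
        scan.entries[n] = ScanEntry(n_states=n, fit=best, bic=bic(best), seeds_tried=seeds)
        log.debug(
            "scan %s/%s N=%d logL=%.2f BIC=%.2f",
            group, image_id, n, best.log_likelihood, scan.entries[n].bic,
        )
    return scan


def repair_discontinuities(
    scan: ModelScan,
    sequences,
    extra_restarts: int = DEFAULT_EXTRA_RESTARTS,
    base_seed: int = 0,
    **fit_kwargs,
) -> ModelScan:
    """Re-fit any N whose best log-likelihood falls below that of N-1.

    A nested model can always be matched, so a drop marks a local optimum.
    Extra seeded attempts are run at the offending N and the best fit kept;
    the procedure iterates until the progression is monotone or the attempt
    budget is exhausted. A better fit is never discarded, so applying the
    repair twice equals applying it once.
    """
    ns = scan.n_range
    for round_idx in range(1, _MAX_REPAIR_ROUNDS + 1):
        broken = [
            n
            for prev, n in zip(ns, ns[1:])
            if scan.loglik(n) < scan.loglik(prev)
        ]
        if not broken:
            scan.discontinuities = []
            return scan
        for n in broken:
            entry = scan.entries[n]
            for a in range(extra_restarts):
                seed = derive_seed(base_seed, n, 1000 * round_idx + a)
                entry.seeds_tried.append(seed)
                fit = _attempt(sequences, n, seed, attempt_idx=1 + a, **fit_kwargs)
                if fit is not None and fit.log_likelihood > entry.fit.log_likelihood:
                    entry.fit = fit
                    entry.bic = bic(fit)
    scan.discontinuities = [
        n for prev, n in zip(ns, ns[1:]) if scan.loglik(n) < scan.loglik(prev)
    ]
    if scan.discontinuities:
        log.warning(
            "scan %s/%s: discontinuities remain at N=%s after repair",
            scan.group, scan.image_id, scan.discontinuities,
        )
    return scan


def select_model(scan: ModelScan) -> FitResult:
    """The minimum-BIC fit of the scan; ties broken toward fewer states."""
    return scan.entries[scan.selected_n].fit


def write_scan_report(scans: list[ModelScan], path) -> None:
    """Scan report CSV: group, image_id, n_states, log_likelihood, bic, selected, seeds_tried."""
    pd.concat([s.to_frame() for s in scans], ignore_index=True).to_csv(path, index=False)
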