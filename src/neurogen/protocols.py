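"""Maturation protocols for the biologically plausible network.

The neurogenesis paradigm runs in stages:

1. *Pretraining* — an adult-stage network is trained on the familiar
   pattern classes until its feedforward weights converge; cells that
   develop selectivity are then frozen (mature), the rest are unresponsive.
2. *Birth* — unresponsive units are replaced by newborn cells: zero
   feedforward weights, excitatory GABAergic input (depolarizing, because of
   the high NKCC1/KCC2 ratio of immature cells), no output to interneurons,
   threshold pinned at zero.
3. *Early (cooperative) phase* — the novel class is interspersed with the
   familiar ones; lateral excitation lets newborn cells fire with the mature
   winners, so their receptive fields grow toward the average of whatever
   drives the network.
4. *GABA-switch* — at ~3 weeks of maturation GABAergic input flips from
   depolarizing to hyperpolarizing: the same interneuron connections change
   sign, newborn cells wire their output onto interneurons, and threshold
   adaptation begins.
5. *Late (competitive) phase* — under lateral inhibition, newborn cells
   specialize on the patterns the mature population does not capture, i.e.
   the novel class.

Three controls strip out the two-phase maturation: simultaneous training of
all classes from scratch (control 1); unresponsive units kept plastic with
their weights and wiring intact (control 2); all units kept plastic
(control 3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import PatternSet
from .network import (MaturationStage, NetworkConfig, NetworkState,
                      converge_rates, init_network)
from .plasticity import PlasticityConfig, hebbian_update, threshold_update

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentPlan",
    "NeurogenesisResult",
    "pretrain",
    "classify_units",
    "birth_newborns",
    "gaba_switch",
    "run_neurogenesis",
    "run_control",
]

#: rate (in units of 10 Hz) above which a cell counts as responsive; 0.1 = 1 Hz
SELECTIVITY_THRESHOLD = 0.1

_PLASTIC_STAGES = (MaturationStage.MATURE_PLASTIC,
                   MaturationStage.NEWBORN_EARLY,
                   MaturationStage.NEWBORN_LATE)
# stages whose firing threshold adapts toward the reference rate; the rule
# belongs to late-phase maturation (mature cells may opt in, but for a cell
# that never wins, b + eta_b (nu - nu0) decreases without bound and the cell
# eventually fires for everything, so the opt-in is off by default)
_B_ADAPTIVE_STAGES = (MaturationStage.NEWBORN_LATE,)


@dataclass
class ExperimentPlan:
    """Declarative description of one neurogenesis experiment."""

    pretrain_classes: tuple = (0, 1)
    novel_classes: tuple = (2,)
    pretrain_epochs: int = 40
    early_epochs: int = 1
    late_epochs: int = 1
    replacement: int | str = "all"   # "all" unresponsive units, or a count
    seed: int = 0
    control: str | None = None       # None | control1 | control2 | control3
    novel_start_fraction: float = 0.0  # where in the early epoch novelty starts
    eta_maturation: float | None = None  # newborn learning rate, if different

    def __post_init__(self) -> None:
        if min(self.pretrain_epochs, self.early_epochs, self.late_epochs) < 1:
            raise ValueError("all epoch counts must be >= 1")
        if self.control not in (None, "control1", "control2", "control3"):
            raise ValueError(f"unknown control variant {self.control!r}")
        if not 0.0 <= self.novel_start_fraction < 1.0:
            raise ValueError("novel_start_fraction must lie in [0, 1)")


@dataclass
class NeurogenesisResult:
    """State and per-phase logs from a neurogenesis (or control) run."""

    state: NetworkState
    selective: np.ndarray
    unresponsive: np.ndarray
    newborn: np.ndarray
    newborn_norms: dict = field(default_factory=dict)    # phase -> trajectory
    newborn_active_frac: dict = field(default_factory=dict)
    snapshots: dict = field(default_factory=dict)        # phase -> W copy
    state_snapshots: dict = field(default_factory=dict)  # phase -> full state


def _plastic_mask(state: NetworkState) -> np.ndarray:
    return np.array([s in _PLASTIC_STAGES for s in state.stage])


def _train_sequence(state: NetworkState, patterns: np.ndarray, order,
                    net_cfg: NetworkConfig, plast_cfg: PlasticityConfig,
                    log_newborn: np.ndarray | None = None,
                    log_every: int = 200,
                    adapt_mature_b: bool = False):
    """Present patterns in ``order``; converge rates and apply plasticity.

    Returns (norm trajectory, active-fraction trajectory) for the cells in
    ``log_newborn`` sampled every ``log_every`` presentations (empty lists
    when no logging is requested).
    """
    plastic = _plastic_mask(state)
    b_stages = _B_ADAPTIVE_STAGES + (
        (MaturationStage.MATURE_PLASTIC,) if adapt_mature_b else ())
    adapt_b = np.array([s in b_stages for s in state.stage])
    norms, active = [], []
    for n, idx in enumerate(order):
        x = patterns[idx]
        resp = converge_rates(state, x, net_cfg)
        if plastic.any():
            state.W[plastic] = hebbian_update(
                state.W[plastic], x, resp.nu[plastic], plast_cfg)
        if adapt_b.any():
            state.b[adapt_b] = threshold_update(
                state.b[adapt_b], resp.nu[adapt_b], plast_cfg)
        if log_newborn is not None and (n % log_every == 0
                                        or n == len(order) - 1):
            norms.append(np.linalg.norm(state.W[log_newborn], axis=1).mean())
            active.append(float(np.mean(
                resp.nu[log_newborn] > SELECTIVITY_THRESHOLD)))
    return norms, active


def pretrain(state: NetworkState, patterns: PatternSet, epochs: int,
             net_cfg: NetworkConfig, plast_cfg: PlasticityConfig,
             rng: np.random.Generator | int | None = None,
             adapt_mature_b: bool = False) -> NetworkState:
    """Train all plastic cells on ``patterns`` for ``epochs`` epochs.

    Each epoch presents every pattern once in a freshly shuffled order;
    after each presentation the rates are converged and the plasticity and
    threshold rules applied.  ``adapt_mature_b`` additionally applies the
    threshold rule to mature plastic cells.
    """
    rng = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(rng) if rng is not None else state.rng)
    for _ in range(epochs):
        order = rng.permutation(patterns.n_patterns)
        _train_sequence(state, patterns.X, order, net_cfg, plast_cfg,
                        adapt_mature_b=adapt_mature_b)
    return state


def classify_units(state: NetworkState, patterns: PatternSet,
                   net_cfg: NetworkConfig) -> tuple[np.ndarray, np.ndarray]:
    """Partition cells into (selective, unresponsive) index arrays.

    A cell is selective iff its converged rate exceeds 1 Hz (nu > 0.1) for
    at least one training pattern.
    """
    max_rate = np.zeros(len(state.W))
    for x in patterns.X:
        resp = converge_rates(state, x, net_cfg)
        max_rate = np.maximum(max_rate, resp.nu)
    selective = np.flatnonzero(max_rate > SELECTIVITY_THRESHOLD)
    unresponsive = np.flatnonzero(max_rate <= SELECTIVITY_THRESHOLD)
    return selective, unresponsive


def birth_newborns(state: NetworkState, indices, net_cfg: NetworkConfig,
                   unresponsive=None, force: bool = False) -> NetworkState:
    """Replace the units in ``indices`` by early-phase newborn cells.

    Feedforward rows are zeroed (no glutamatergic input yet); GABAergic
    input is re-sampled with *positive* (depolarizing) sign; output to
    interneurons is removed; thresholds are pinned at zero.
    """
    indices = np.atleast_1d(np.asarray(indices, dtype=int))
    if unresponsive is not None and not force:
        bad = np.setdiff1d(indices, np.asarray(unresponsive))
        if bad.size:
            raise ValueError(
                f"refusing to replace selective units {bad.tolist()} "
                "(pass force=True to override)")
    for i in indices:
        state.W[i] = 0.0
        row_mask = state.rng.uniform(size=state.mask_ei.shape[1]) < net_cfg.p_ei
        state.mask_ei[i] = row_mask
        state.w_ei[i] = np.where(row_mask, net_cfg.w_ei, 0.0)   # excitatory
        state.w_ie[:, i] = 0.0
        state.b[i] = 0.0
        state.stage[i] = MaturationStage.NEWBORN_EARLY
    return state


def gaba_switch(state: NetworkState, indices,
                net_cfg: NetworkConfig) -> NetworkState:
    """Flip GABAergic input of early-phase newborns to inhibitory.

    The existing interneuron->cell connections keep their mask but change
    sign; output connections onto interneurons are sampled Bernoulli(p_ie);
    threshold adaptation is enabled by moving the cell to the late stage.
    """
    indices = np.atleast_1d(np.asarray(indices, dtype=int))
    for i in indices:
        if state.stage[i] is not MaturationStage.NEWBORN_EARLY:
            raise ValueError(
                f"unit {i} is {state.stage[i]}, not an early-phase newborn")
        state.w_ei[i] = np.where(state.mask_ei[i], -net_cfg.w_ei, 0.0)
        col_mask = state.rng.uniform(size=state.w_ie.shape[0]) < net_cfg.p_ie
        state.w_ie[:, i] = np.where(col_mask, net_cfg.w_ie, 0.0)
        state.stage[i] = MaturationStage.NEWBORN_LATE
    return state


def _mixed_order(rng: np.random.Generator, n_familiar: int, n_novel: int,
                 novel_start_fraction: float) -> np.ndarray:
    """Presentation order over familiar indices [0, n_familiar) and novel
    indices [n_familiar, n_familiar+n_novel), with the novel patterns
    interspersed only after ``novel_start_fraction`` of the sequence."""
    familiar = rng.permutation(n_familiar)
    novel = n_familiar + rng.permutation(n_novel)
    if novel_start_fraction == 0.0:
        return rng.permutation(np.concatenate([familiar, novel]))
    split = int(round(novel_start_fraction * n_familiar))
    head = familiar[:split]
    tail = rng.permutation(np.concatenate([familiar[split:], novel]))
    return np.concatenate([head, tail])


def run_neurogenesis(plan: ExperimentPlan, train: PatternSet,
                     net_cfg: NetworkConfig, plast_cfg: PlasticityConfig,
                     state: NetworkState | None = None,
                     log_every: int = 200) -> NeurogenesisResult:
    """Execute the full two-phase neurogenesis paradigm.

    Pretrain on the familiar classes, freeze selective cells, replace
    unresponsive ones by newborns, run the early (cooperative) epoch(s) with
    the novel class interspersed, apply the GABA-switch, and run the late
    (competitive) epoch(s).
    """
    if plan.control is not None:
        return run_control(plan, train, net_cfg, plast_cfg, state=state)
    rng = np.random.default_rng([2, plan.seed])
    if state is None:
        state = init_network(net_cfg, np.random.default_rng([1, plan.seed]))

    familiar = train.subset(plan.pretrain_classes)
    pretrain(state, familiar, plan.pretrain_epochs, net_cfg, plast_cfg, rng)
    selective, unresponsive = classify_units(state, familiar, net_cfg)

    # freeze mature cells, pick the replacement cohort
    for i in selective:
        state.stage[i] = MaturationStage.MATURE_FIXED
    if plan.replacement == "all":
        cohort = unresponsive
    else:
        count = int(plan.replacement)
        if count > unresponsive.size:
            raise ValueError(
                f"cannot replace {count} units, only {unresponsive.size} "
                "are unresponsive")
        row_norms = np.linalg.norm(state.W[unresponsive], axis=1)
        cohort = unresponsive[np.argsort(row_norms)[:count]]
    birth_newborns(state, cohort, net_cfg, unresponsive=unresponsive)

    if plan.eta_maturation is not None:
        plast_cfg = replace(plast_cfg, eta=plan.eta_maturation)

    novel = train.subset(plan.novel_classes)
    mixed_X = np.vstack([familiar.X, novel.X])
    result = NeurogenesisResult(state, selective, unresponsive, cohort)
    result.snapshots["pretrain"] = state.W.copy()

    newborn_mask = np.zeros(len(state.W), dtype=bool)
    newborn_mask[cohort] = True
    for phase, epochs in (("early", plan.early_epochs),
                          ("late", plan.late_epochs)):
        norms, active = [], []
        for _ in range(epochs):
            order = _mixed_order(rng, familiar.n_patterns, novel.n_patterns,
                                 plan.novel_start_fraction)
            n, a = _train_sequence(state, mixed_X, order, net_cfg, plast_cfg,
                                   log_newborn=newborn_mask,
                                   log_every=log_every)
            norms.extend(n)
            active.extend(a)
        result.newborn_norms[phase] = np.array(norms)
        result.newborn_active_frac[phase] = np.array(active)
        result.snapshots[phase] = state.W.copy()
        result.state_snapshots[phase] = state.copy()
        if phase == "early":
            gaba_switch(state, cohort, net_cfg)
    state.validate()
    return result


def run_control(plan: ExperimentPlan, train: PatternSet,
                net_cfg: NetworkConfig, plast_cfg: PlasticityConfig,
                state: NetworkState | None = None) -> NeurogenesisResult:
    """Run one of the three control variants (no GABA-switch machinery)."""
    if plan.control not in ("control1", "control2", "control3"):
        raise ValueError(f"unknown control variant {plan.control!r}")
    rng = np.random.default_rng([2, plan.seed])
    if state is None:
        state = init_network(net_cfg, np.random.default_rng([1, plan.seed]))
    all_classes = tuple(plan.pretrain_classes) + tuple(plan.novel_classes)
    n_epochs = plan.early_epochs + plan.late_epochs

    if plan.control == "control1":
        # all classes pretrained simultaneously from random weights
        pretrain(state, train.subset(all_classes), plan.pretrain_epochs,
                 net_cfg, plast_cfg, rng)
        selective, unresponsive = classify_units(
            state, train.subset(all_classes), net_cfg)
        return NeurogenesisResult(state, selective, unresponsive,
                                  np.array([], dtype=int))

    familiar = train.subset(plan.pretrain_classes)
    pretrain(state, familiar, plan.pretrain_epochs, net_cfg, plast_cfg, rng)
    selective, unresponsive = classify_units(state, familiar, net_cfg)
    if plan.control == "control2":
        # selective cells frozen; unresponsive stay plastic with their
        # weights and wiring unchanged
        for i in selective:
            state.stage[i] = MaturationStage.MATURE_FIXED
    # control3: every cell keeps plastic feedforward weights

    result = NeurogenesisResult(state, selective, unresponsive,
                                np.array([], dtype=int))
    result.snapshots["pretrain"] = state.W.copy()
    pretrain(state, train.subset(all_classes), n_epochs, net_cfg,
             plast_cfg, rng)
    result.snapshots["late"] = state.W.copy()
    return result
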