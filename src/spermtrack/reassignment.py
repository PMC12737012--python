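"""EKF identity-verification layer on top of the baseline tracker.

The baseline tracker mints a fresh id whenever an object reappears
after a detection dropout longer than its association can bridge —
the dominant cause of identity fragmentation and overcounting in
dense microscopy video.  This layer maintains one heading-aware EKF
per *final* identity and a mapping from baseline ids to final ids.
When the baseline emits an unknown id, the new detection's centroid is
compared against the rolled-forward prediction of every recently lost
identity; if the nearest prediction is within the gating threshold the
old identity is revived and the baseline id permanently aliased to it,
otherwise a new final id is minted.  Identities unseen for more than
``max_lost`` frames are retired for good, so stale tracks can never
capture a new object.

Matching is greedy per detection in detection order; a revived
identity is immediately removed from the lost registry, so no final id
can be emitted twice in one frame.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from spermtrack.core_io import BBox
from spermtrack.ekf import (
    EKFNoiseConfig,
    EKFState,
    ekf_init,
    ekf_loss,
    ekf_predict,
    ekf_update,
)

__all__ = ["ReassignConfig", "LostRegistry", "IdMap", "Reassigner", "match_lost"]

logger = logging.getLogger(__name__)


@dataclass
class ReassignConfig:
    """Gating parameters of the reassignment layer.

    ``delta`` is the loss threshold in pixels: a reappearing detection
    is re-assigned a lost identity only if the Euclidean distance to
    that identity's predicted position is below it (default 30 px,
    the value that balances identity recovery against false
    reassignment).  ``gate_mode='covariance_scaled'`` replaces the
    fixed gate with ``gate_coeff * sqrt(trace of the position block of
    P)``, letting the gate widen with prediction uncertainty.
    """

    delta: float = 30.0
    max_lost: int = 30
    gate_mode: str = "fixed"  # "fixed" | "covariance_scaled"
    gate_coeff: float = 2.0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.max_lost < 1:
            raise ValueError("max_lost must be >= 1")
        if self.gate_mode not in ("fixed", "covariance_scaled"):
            raise ValueError(f"unknown gate_mode {self.gate_mode!r}")


@dataclass
class LostRegistry:
    """Lost identities: final_id -> (EKF state, last frame seen)."""

    entries: dict[int, EKFState] = field(default_factory=dict)

    def __contains__(self, final_id: int) -> bool:
        return final_id in self.entries


@dataclass
class IdMap:
    """Alias table from baseline-tracker ids to final ids."""

    mapping: dict[int, int] = field(default_factory=dict)
    next_final_id: int = 1


def _effective_gate(state: EKFState, cfg: ReassignConfig) -> float:
    if cfg.gate_mode == "fixed":
        return cfg.delta
    pos_var = float(state.P[0, 0] + state.P[1, 1])
    return cfg.gate_coeff * math.sqrt(max(pos_var, 0.0))


def match_lost(
    z: tuple[float, float],
    registry: LostRegistry,
    frame: int,
    cfg: ReassignConfig,
    noise_cfg: EKFNoiseConfig,
) -> int | None:
    """Find the lost identity whose prediction best explains ``z``.

    Each lost EKF is rolled forward to ``frame`` with one predict per
    elapsed frame (so its uncertainty grows with the gap) and the one
    with minimum positional loss is returned — provided that loss is
    below the effective gate.  Ties break toward the lower final id.
    The registry is not mutated.
    """
    best_id: int | None = None
    best_loss = math.inf
    for final_id in sorted(registry.entries):
        state = registry.entries[final_id]
        rolled = _roll_forward(state, frame, noise_cfg)
        loss = ekf_loss(rolled, z)
        if loss < _effective_gate(rolled, cfg) and loss < best_loss:
            best_id = final_id
            best_loss = loss
    return best_id


def _roll_forward(state: EKFState, frame: int, noise_cfg: EKFNoiseConfig) -> EKFState:
    rolled = state.copy()
    for _ in range(max(frame - state.last_frame, 0)):
        rolled = ekf_predict(rolled, noise_cfg)
    return rolled


class Reassigner:
    """Stateful two-layer verification; feed it each frame's baseline output."""

    def __init__(
        self,
        cfg: ReassignConfig | None = None,
        noise_cfg: EKFNoiseConfig | None = None,
    ):
        self.cfg = cfg or ReassignConfig()
        self.noise_cfg = noise_cfg or EKFNoiseConfig()
        self.id_map = IdMap()
        self.registry = LostRegistry()
        self.active: dict[int, EKFState] = {}
        self._last_frame = 0
        self.n_merges = 0  # reassignment events (identity revivals)
        self.n_new = 0
        self.n_pruned = 0

    def process_frame(
        self, frame: int, base_outputs: list[tuple[int, BBox]]
    ) -> list[tuple[int, BBox, EKFState]]:
        """Resolve baseline ids to final ids and run one EKF cycle each.

        For every baseline output: a known baseline id keeps its final
        id; an unknown one either revives the nearest recoverable lost
        identity or mints a new final id.  The resolved identity's EKF
        is rolled forward to this frame and updated with the box
        centroid.  Box size passes through from the baseline; the EKF
        filters the centroid only.
        """
        if frame <= self._last_frame:
            raise ValueError(
                f"frames must be strictly increasing, got {frame} after {self._last_frame}"
            )
        self._last_frame = frame

        outputs: list[tuple[int, BBox, EKFState]] = []
        emitted: set[int] = set()
        for base_id, box in base_outputs:
            z = box.center
            if base_id in self.id_map.mapping:
                final_id = self.id_map.mapping[base_id]
                if final_id not in self.active:
                    # the baseline itself bridged a short gap: the final
                    # id sits in the lost registry; restore it silently
                    self.active[final_id] = self.registry.entries.pop(final_id)
            else:
                final_id = match_lost(z, self.registry, frame, self.cfg, self.noise_cfg)
                if final_id is not None:
                    # revive: restore the lost EKF and alias the new base id;
                    # stale aliases from before the loss are dropped so a
                    # final id can never be carried by two live base ids
                    self.active[final_id] = self.registry.entries.pop(final_id)
                    fid = final_id
                    self.id_map.mapping = {
                        b: f for b, f in self.id_map.mapping.items() if f != fid
                    }
                    self.n_merges += 1
                    logger.debug(
                        "frame %d: base id %d merged into final id %d",
                        frame, base_id, final_id,
                    )
                else:
                    final_id = self.id_map.next_final_id
                    self.id_map.next_final_id += 1
                    self.active[final_id] = ekf_init(z, self.noise_cfg, frame=frame)
                    self.n_new += 1
                    logger.debug("frame %d: new final id %d", frame, final_id)
                self.id_map.mapping[base_id] = final_id

            if final_id in emitted:
                raise AssertionError(
                    f"final id {final_id} resolved twice at frame {frame}"
                )
            emitted.add(final_id)

            state = _roll_forward(self.active[final_id], frame, self.noise_cfg)
            state = ekf_update(state, z, self.noise_cfg)
            state.last_frame = frame
            self.active[final_id] = state
            outputs.append((final_id, box, state))

        self.retire_and_prune(frame, emitted)
        return outputs

    def retire_and_prune(self, frame: int, emitted: set[int]) -> None:
        """Move unseen identities to the lost registry; drop stale ones.

        An identity absent for exactly ``max_lost`` frames is still
        eligible for revival; one frame more and it is deleted
        permanently together with its baseline aliases.
        """
        for final_id in list(self.active):
            if final_id not in emitted:
                self.registry.entries[final_id] = self.active.pop(final_id)
                logger.debug("frame %d: final id %d retired to lost", frame, final_id)
        stale = [
            fid
            for fid, state in self.registry.entries.items()
            if frame - state.last_frame > self.cfg.max_lost
        ]
        for fid in stale:
            del self.registry.entries[fid]
            self.n_pruned += 1
            logger.debug("frame %d: final id %d pruned", frame, fid)
        if stale:
            doomed = set(stale)
            self.id_map.mapping = {
                b: f for b, f in self.id_map.mapping.items() if f not in doomed
            }
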