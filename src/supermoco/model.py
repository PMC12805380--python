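"""Model/Results interface over the reconstruction pipeline.

:class:`SuperMoCoModel` is built from the acquired data (raw k-space,
coil maps, optional trained networks); :meth:`SuperMoCoModel.fit` runs
the full motion-corrected super-resolving reconstruction and returns a
:class:`ReconResults` carrying the image estimate, per-stage
diagnostics, and a text summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .admm import Networks, ReconConfig, super_moco_modl_reconstruct
from .evaluation import ROIMask, scaled_roi_mse, scaled_roi_ssim
from .phantom import RawKSpace

__all__ = ["SuperMoCoModel", "ReconResults"]


class SuperMoCoModel:
    """Motion-corrected, super-resolving model-based reconstruction.

    Parameters
    ----------
    raw : RawKSpace
        Multi-coil acquisition with trajectory and navigators.
    coil_maps : (Nc, X, Y, Z) complex array
        Normalized coil sensitivities on the target grid.
    networks : Networks, optional
        Trained motion-estimation and denoiser networks; either may be
        None (identity motion / plain model-based reconstruction).
    config : ReconConfig, optional
    """

    def __init__(self, raw: RawKSpace, coil_maps: np.ndarray,
                 networks: Networks | None = None,
                 config: ReconConfig | None = None):
        self.raw = raw
        self.coil_maps = np.asarray(coil_maps, dtype=complex)
        self.networks = networks or Networks()
        self.config = config or ReconConfig()

    @classmethod
    def from_file(cls, path, coil_maps, **kw) -> "SuperMoCoModel":
        from .io import load_raw

        return cls(load_raw(path), coil_maps, **kw)

    def fit(self) -> "ReconResults":
        diag: dict = {}
        image = super_moco_modl_reconstruct(self.raw, self.coil_maps,
                                            self.networks, self.config, diag)
        return ReconResults(model=self, image=image, diagnostics=diag)


@dataclass
class ReconResults:
    """Reconstruction estimate with diagnostics."""

    model: SuperMoCoModel
    image: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def zero_filled(self) -> np.ndarray:
        """Zero-filled image of the reference respiratory bin."""
        plan = self.diagnostics["plan"]
        return self.diagnostics["zero_filled_bins"][plan.reference_bin]

    def evaluate(self, reference: np.ndarray, roi: ROIMask | None = None) -> dict:
        roi = roi or ROIMask.central_box(self.image.shape)
        mse, a = scaled_roi_mse(self.image, reference, roi)
        ssim, s = scaled_roi_ssim(self.image, reference, roi)
        return {"mse": mse, "ssim": ssim, "mse_scale": a, "ssim_scale": s}

    def summary(self) -> str:
        cfg = self.model.config
        plan = self.diagnostics.get("plan")
        lines = [
            "Super-MoCo-MoDL reconstruction",
            "=" * 46,
            f"grid (x, y, z)        : {self.image.shape}",
            f"respiratory bins      : {cfg.n_bins} (reference = "
            f"{plan.reference_bin if plan is not None else '-'})",
            f"ADMM iterations       : {cfg.n_admm} (lambda={cfg.lam}, mu={cfg.mu})",
            f"CG / SENSE iterations : {cfg.n_cg} / {cfg.n_sense}",
            f"patch thickness       : {cfg.patch.thickness} "
            f"(discard {cfg.patch.discard}, overlap {cfg.patch.overlap})",
        ]
        acc = self.diagnostics.get("acceleration")
        if acc is not None:
            lines.append(
                f"acceleration          : VD-CASPR {acc[0]:.2f} x SR {acc[1]:.2f} "
                f"= overall {acc[2]:.1f}"
            )
        patches = self.diagnostics.get("patches") or []
        if patches and patches[0].get("cg_residuals"):
            res0 = patches[0]["cg_residuals"]
            first, last = res0[0][0], res0[-1][-1]
            lines.append(f"CG residual (patch 0) : {first:.3e} -> {last:.3e}")
        if patches and patches[0].get("primal_residuals"):
            pr = patches[0]["primal_residuals"]
            lines.append(f"ADMM primal residuals : " + ", ".join(f"{v:.3e}" for v in pr))
        return "\n".join(lines)

    def save_nifti(self, path, phase_path=None) -> None:
        from .io import save_nifti

        save_nifti(path, self.image, self.model.raw.voxel_size_mm, phase_path)

    def plot_slices(self, path=None):
        """Orthogonal mid-slices of the magnitude image."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        mag = np.abs(self.image)
        fig, axes = plt.subplots(1, 3, figsize=(10, 4))
        views = [mag[mag.shape[0] // 2], mag[:, mag.shape[1] // 2], mag[:, :, mag.shape[2] // 2]]
        for ax, v, name in zip(axes, views, ["axial (y-z)", "coronal (x-z)", "sagittal (x-y)"]):
            ax.imshow(v, cmap="gray")
            ax.set_title(name)
            ax.axis("off")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
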