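"""Canonical desk-scale end-to-end demonstration conditions.

One clean phantom — one capillary network and two sinus networks, no
anastomoses, no artefacts — rendered as 21 sections of 256×256 px covering a
200 × 200 × 140 μm block, reconstructed with the default filter chain.  The
demo interpolates to 3.5 μm z-planes (two interpolated planes per section
gap) rather than the full-scale 1 μm so that the whole run, including the
two ray-cast analyses, completes in about two minutes on one CPU; thresholds
given in μm are spacing-aware and unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PipelineConfig, SectionStack
from .phantom import (
    DefectRates,
    PhantomSpec,
    PhantomTruth,
    RecoveryReport,
    evaluate_recovery,
    generate_network,
    render_sections,
)
from .pipeline import PipelineResult, run_pipeline

DEMO_DOMAIN = (200.0, 200.0, 140.0)  # μm
DEMO_SECTION_PX = 256
DEMO_Z_SPACING = 7.0  # μm per section


def demo_spec(seed: int = 7) -> PhantomSpec:
    """Clean phantom: 1 capillary + 2 sinus networks, no cross-links, no defects.

    Sinus flattening is disabled so that caliber classes are unambiguous
    ground truth (a flat sinus legitimately reads thin from its broad side).
    """
    return PhantomSpec(
        domain_size=DEMO_DOMAIN,
        n_capillary_networks=1,
        n_sinus_networks=2,
        n_cross_connections=0,
        sinus_flatness_max=1.0,
        defect_rates=DefectRates(0.0, 0.0, 0.0),
        seed=seed,
    )


def demo_config(seed: int = 7) -> PipelineConfig:
    return PipelineConfig(interp_target_z=3.5, seed=seed)


@dataclass
class DemoResult:
    truth: PhantomTruth
    stack: SectionStack
    result: PipelineResult
    recovery: RecoveryReport


def run_demo(seed: int = 7, outdir=None) -> DemoResult:
    """Generate the demo phantom, run the pipeline, score the recovery."""
    spec = demo_spec(seed)
    truth = generate_network(spec)
    stack = render_sections(
        truth, spec, xy_spacing=DEMO_DOMAIN[0] / DEMO_SECTION_PX, z_spacing=DEMO_Z_SPACING
    )
    cfg = demo_config(seed)
    result = run_pipeline(cfg, stack, outdir=outdir)
    if result.sdf_field is not None and result.sdf_components is not None:
        recovery = evaluate_recovery(
            truth,
            result.sdf_mesh,
            result.sdf_components.component_id,
            result.sdf_field.values,
            sdf_center=cfg.sdf_center,
        )
    else:
        recovery = evaluate_recovery(truth, None, np.zeros(0, int), np.zeros(0))
    return DemoResult(truth, stack, result, recovery)
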