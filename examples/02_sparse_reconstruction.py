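"""Emulate every-second-slice manual annotation and reconstruct densely.

Manual lung segmentation is typically drawn on every second axial slice;
the full 3D mask is then rebuilt by shape-based interpolation of signed
distance maps along the cranial-caudal axis.  This script shows the
volume error that the sparsify-reconstruct round trip introduces on a
realistic phantom (a fraction of a percent).
"""

from lungmorph import PhantomSpec, make_breath_pair, reconstruct_dense, sparsify

pair, _ = make_breath_pair(PhantomSpec(seed=7), subject_id="demo")

for phase_name in ("expiration", "inspiration"):
    dense = getattr(pair, phase_name)
    annotation = sparsify(dense, step=2)
    rebuilt = reconstruct_dense(annotation)
    v_dense = dense.volume_ml
    v_rebuilt = rebuilt.volume_ml
    err = 100 * abs(v_rebuilt - v_dense) / v_dense
    print(f"{phase_name:>11}: {len(annotation.indices)} of "
          f"{dense.shape[2]} slices annotated, "
          f"volume {v_dense:.1f} -> {v_rebuilt:.1f} ml ({err:.2f}% error)")
# Annotated slices pass through reconstruction unchanged; only the
# skipped slices are interpolated, so the error stays well under 2%.
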