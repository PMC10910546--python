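# Per-tilt-series recipe: alignment + weighted back-projection, then
# denoising, then tomogram image panels. Triggered by the coordination
# server once every tilt in the series is motion-corrected; the
# movie -> tilt-series aggregation is deliberately not an edge here.
name: reconstruct
domain: tilt_series
entry: tomo_align_recon
vertices:
  tomo_align_recon:
    service: tomo_align_recon
    parameters:
      thickness: 64
  denoise:
    service: denoise
    parameters:
      strength: 1.0
  images:
    service: images
    parameters:
      kind: volume
edges:
  tomo_align_recon: [denoise]
  denoise: [images]
  images: []
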