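# Per-movie preprocessing recipe: motion correction fans out to CTF
# estimation and thumbnail generation. One run per transferred movie.
name: preprocess
domain: movie
entry: motioncorr
vertices:
  motioncorr:
    service: motioncorr
    parameters: {}
  ctffind:
    service: ctffind
    parameters: {}
  images:
    service: images
    parameters:
      kind: micrograph
edges:
  motioncorr: [ctffind, images]
  ctffind: []
  images: []
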