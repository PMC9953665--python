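{
  "title": "isoscope run manifest",
  "required": {
    "version": "string",
    "seed": "integer",
    "parameters": "object",
    "stages": "object",
    "row_counts": "object"
  }
}
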