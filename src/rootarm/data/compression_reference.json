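{
  "description": "Published complexity trajectory of the reference YOLOv8-Seg-n compression study (2-class, 640x640): baseline network, then five iterations of ~10% BN-gamma channel pruning with 20-epoch fine-tuning. Used as input data for compression-arithmetic reporting.",
  "baseline": {"params_m": 3.26, "flops_g": 12.1, "weight_mb": 6.8},
  "iterations": {
    "params_m": [3.26, 2.89, 2.55, 2.28, 2.03, 1.81],
    "flops_g": [12.1, 11.0, 10.2, 9.5, 8.8, 8.3],
    "weight_mb": [6.8, 6.2, 5.7, 5.2, 4.7, 4.2]
  },
  "final": {"params_m": 1.81, "flops_g": 8.3, "weight_mb": 4.2}
}
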