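{
  "description": "Per-fold five-fold cross-validation values from the published PET/CT ovarian-tumor study this package re-implements. Used to verify cross-fold aggregation and significance testing against the published summary rows.",
  "segmentation_baselines": {
    "FCN": {
      "dice": [0.642, 0.632, 0.655, 0.629, 0.614],
      "iou": [0.472, 0.462, 0.487, 0.459, 0.443],
      "ahd_px": [18.9, 19.4, 18.2, 19.6, 20.3]
    },
    "Deeplabv3": {
      "dice": [0.721, 0.745, 0.752, 0.756, 0.748],
      "iou": [0.564, 0.594, 0.602, 0.608, 0.598],
      "ahd_px": [12.7, 10.9, 10.4, 10.1, 10.7]
    },
    "U-Net": {
      "dice": [0.677, 0.691, 0.672, 0.658, 0.636],
      "iou": [0.511, 0.527, 0.505, 0.489, 0.465],
      "ahd_px": [16.2, 15.3, 16.5, 17.1, 18.0]
    },
    "U-Net-VGG": {
      "dice": [0.731, 0.761, 0.742, 0.755, 0.750],
      "iou": [0.576, 0.614, 0.590, 0.607, 0.610],
      "ahd_px": [12.0, 10.1, 11.3, 10.2, 10.8]
    },
    "U-Net-MobileNetv3": {
      "dice": [0.750, 0.774, 0.789, 0.747, 0.803],
      "iou": [0.610, 0.632, 0.651, 0.597, 0.670],
      "ahd_px": [10.8, 9.2, 8.3, 11.0, 7.5]
    },
    "Segmentation model": {
      "dice": [0.790, 0.812, 0.839, 0.786, 0.825],
      "iou": [0.653, 0.683, 0.721, 0.647, 0.703],
      "ahd_px": [6.2, 5.1, 4.3, 6.4, 4.8]
    }
  },
  "carvemix_scaling": {
    "without": {
      "dice": [0.790, 0.812, 0.839, 0.786, 0.825],
      "iou": [0.653, 0.683, 0.721, 0.647, 0.703],
      "ahd_px": [6.2, 5.1, 4.3, 6.4, 4.8]
    },
    "m_plus_1m": {
      "dice": [0.805, 0.809, 0.790, 0.821, 0.810],
      "iou": [0.670, 0.677, 0.653, 0.695, 0.678],
      "ahd_px": [5.3, 5.5, 6.2, 4.6, 5.4]
    },
    "m_plus_1.5m": {
      "dice": [0.806, 0.817, 0.798, 0.823, 0.804],
      "iou": [0.672, 0.689, 0.664, 0.698, 0.670],
      "ahd_px": [5.2, 4.9, 5.8, 4.5, 5.3]
    },
    "m_plus_2m": {
      "dice": [0.813, 0.821, 0.798, 0.827, 0.830],
      "iou": [0.681, 0.695, 0.664, 0.703, 0.707],
      "ahd_px": [4.8, 4.6, 5.8, 4.3, 4.2]
    }
  },
  "loss_ablation": {
    "model": {
      "dice": [0.790, 0.812, 0.839, 0.786, 0.825],
      "iou": [0.653, 0.683, 0.721, 0.647, 0.703],
      "ahd_px": [6.2, 5.1, 4.3, 6.4, 4.8]
    },
    "model_carvemix": {
      "dice": [0.813, 0.821, 0.798, 0.827, 0.830],
      "iou": [0.681, 0.695, 0.664, 0.703, 0.707],
      "ahd_px": [4.8, 4.6, 5.8, 4.3, 4.2]
    },
    "model_carvemix_dicece": {
      "dice": [0.829, 0.835, 0.812, 0.831, 0.824],
      "iou": [0.707, 0.721, 0.683, 0.706, 0.700],
      "ahd_px": [4.0, 3.8, 5.1, 4.2, 4.4]
    }
  },
  "classification_baselines": {
    "ConvNeXt": {
      "acc": [0.911, 0.927, 0.898, 0.878, 0.919],
      "auc": [0.938, 0.951, 0.923, 0.905, 0.945]
    },
    "DenseNet": {
      "acc": [0.902, 0.914, 0.907, 0.890, 0.878],
      "auc": [0.927, 0.936, 0.929, 0.912, 0.903]
    },
    "EfficientNet": {
      "acc": [0.898, 0.910, 0.882, 0.886, 0.898],
      "auc": [0.922, 0.933, 0.908, 0.910, 0.924]
    },
    "Swin-Transformer": {
      "acc": [0.837, 0.825, 0.856, 0.864, 0.858],
      "auc": [0.862, 0.850, 0.881, 0.889, 0.885]
    }
  },
  "mixup_scaling": {
    "without": {
      "acc": [0.911, 0.927, 0.898, 0.878, 0.919],
      "auc": [0.938, 0.951, 0.923, 0.905, 0.945]
    },
    "m_plus_1m": {
      "acc": [0.923, 0.915, 0.907, 0.881, 0.903],
      "auc": [0.949, 0.940, 0.932, 0.908, 0.928]
    },
    "m_plus_1.5m": {
      "acc": [0.928, 0.918, 0.911, 0.863, 0.894],
      "auc": [0.954, 0.943, 0.936, 0.889, 0.919]
    },
    "m_plus_2m": {
      "acc": [0.930, 0.929, 0.922, 0.885, 0.896],
      "auc": [0.956, 0.954, 0.947, 0.910, 0.921]
    }
  },
  "branch_ablation": {
    "KiteNet": {
      "dice": [0.473, 0.426, 0.442, 0.416, 0.461],
      "iou": [0.319, 0.298, 0.311, 0.290, 0.314],
      "ahd_px": [18.6, 19.9, 19.1, 20.0, 18.7]
    },
    "U-Net-MobileNetv3": {
      "dice": [0.750, 0.774, 0.789, 0.747, 0.803],
      "iou": [0.610, 0.632, 0.651, 0.597, 0.670],
      "ahd_px": [10.8, 9.2, 8.3, 11.0, 7.5]
    },
    "Fusion model": {
      "dice": [0.829, 0.835, 0.812, 0.831, 0.824],
      "iou": [0.707, 0.721, 0.683, 0.706, 0.700],
      "ahd_px": [4.0, 3.8, 5.1, 4.2, 4.4]
    }
  }
}
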