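# Reference training configuration for an external YOLO-style segmentation
# detector.  This file is documentation shipped with the package: fishline
# does not train networks.  Users who train a detector elsewhere can plug it
# in through the external-command backend, which exchanges detections as
# JSON lines in original-image coordinates.
model: yolo-seg
input_size: [640, 640]
learning_rate: 0.01
optimizer: sgd
batch_size: 16
max_epochs: 500
early_stopping_patience: 100
iou_threshold: 0.2
train_fraction: 0.7
validation_fraction: 0.3
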