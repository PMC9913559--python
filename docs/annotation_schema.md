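# Annotation XML schema

`radscan.annotations.read_annotations` accepts a small XML dialect for nodule
annotations, plus a tolerant mode for LIDC-style files.  Matching is by local
element name, so namespaces are ignored.

## Native dialect

```xml
<exam>
  <reader id="A">
    <nodule id="n1">
      <malignancy>4</malignancy>          <!-- integer grade 1-5, required -->
      <center z="12.5" y="210" x="305"/>  <!-- voxel or mm coordinates -->
      <diameter_mm>7.5</diameter_mm>      <!-- optional; fallback 1.0 -->
      <solid>true</solid>                 <!-- optional; default true -->
    </nodule>
  </reader>
</exam>
```

- One `<reader>` element per reading session; `id` names the reader.
- Each `<nodule>` needs a `<malignancy>` grade in 1–5.  Records with a
  missing or out-of-range grade are skipped with a `RuntimeWarning`.
- `<center>` carries `z`, `y`, `x` attributes (in that semantic order;
  missing attributes default to 0).

## Tolerant LIDC-style mode

The same reader also understands the corresponding LIDC element names:

| native          | LIDC equivalent                          |
|-----------------|------------------------------------------|
| `reader`        | `readingSession`                         |
| `reader/@id`    | `servicingRadiologistID` (child element) |
| `nodule`        | `unblindedReadNodule`                    |
| `nodule/@id`    | `noduleID` (child element)               |
| `center` attrs  | `imageZposition`, `yCoord`, `xCoord` text elements |

Full LIDC features (per-slice edge maps, blinded reads, non-nodule marks)
are out of scope.

## Multiple readers

When a document contains several reader sessions, only the session that
identifies the **most** nodules is returned — the standard rule for avoiding
duplicate annotations of the same lesion across readers.

## Errors

- Malformed XML raises `lxml.etree.XMLSyntaxError`, which carries the
  offending line number.
- An exam with no sessions or no valid nodules returns an empty list.
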