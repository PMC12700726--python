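# GAM engine: candidate fits, AIC choice, backward removal of
# non-significant smooths, optional per-term grid predictions.
# Interface: Rscript gam_fit.R <dir> with <dir>/data.csv, <dir>/config.json;
# writes <dir>/result.json.
suppressMessages({
  library(mgcv)
  library(jsonlite)
})

args <- commandArgs(trailingOnly = TRUE)
dir <- args[[1]]
cfg <- fromJSON(file.path(dir, "config.json"), simplifyVector = FALSE)
dat <- read.csv(file.path(dir, "data.csv"))

response <- cfg$response
alpha <- if (is.null(cfg$alpha)) 0.05 else cfg$alpha
family_name <- if (is.null(cfg$family)) "gaussian" else cfg$family
fam <- switch(family_name, gaussian = gaussian(), poisson = poisson(),
              stop("unknown family"))
do_stepwise <- if (is.null(cfg$stepwise)) TRUE else isTRUE(cfg$stepwise)
use_select <- if (is.null(cfg$select)) FALSE else isTRUE(cfg$select)

smooth_label <- function(sm) paste0("s(", sm$term, ")")
tensor_label <- function(tn) paste0("ti(", paste(unlist(tn$vars), collapse = ","), ")")

smooth_formula <- function(sm) {
  k <- if (is.null(sm$k)) -1 else sm$k
  bs <- if (is.null(sm$bs)) "tp" else sm$bs
  sprintf("s(%s, k=%d, bs=\"%s\")", sm$term, k, bs)
}
tensor_formula <- function(tn) {
  k <- if (is.null(tn$k)) 5 else tn$k
  sprintf("ti(%s, k=c(%d,%d))", paste(unlist(tn$vars), collapse = ","), k, k)
}

# knots for cyclic smooths (e.g. wind direction on [0, 360))
knots <- list()
for (sm in cfg$smooths) {
  if (!is.null(sm$knots)) knots[[sm$term]] <- unlist(sm$knots)
}

term_defs <- list()
for (sm in cfg$smooths) {
  term_defs[[smooth_label(sm)]] <- smooth_formula(sm)
}
tensor_labels <- character(0)
if (length(cfg$tensors) > 0) {
  for (tn in cfg$tensors) {
    term_defs[[tensor_label(tn)]] <- tensor_formula(tn)
    tensor_labels <- c(tensor_labels, tensor_label(tn))
  }
}
smooth_labels <- vapply(cfg$smooths, smooth_label, "")

build_formula <- function(labels) {
  if (length(labels) == 0) {
    as.formula(paste(response, "~ 1"))
  } else {
    rhs <- paste(vapply(labels, function(l) term_defs[[l]], ""), collapse = " + ")
    as.formula(paste(response, "~", rhs))
  }
}

fit_gam <- function(labels, d) {
  gam(build_formula(labels), data = d, family = fam, method = "REML",
      select = use_select, knots = if (length(knots)) knots else NULL)
}

# mgcv labels smooths like "s(x)" / "ti(x,y)"; match on stripped names
stable_labels <- function(fit) {
  if (length(fit$smooth) == 0) return(character(0))
  vapply(fit$smooth, function(s) s$label, "")
}

term_table <- function(fit) {
  st <- summary(fit)$s.table
  if (is.null(st) || nrow(st) == 0) return(list())
  out <- list()
  for (i in seq_len(nrow(st))) {
    out[[i]] <- list(term = rownames(st)[i],
                     edf = unname(st[i, 1]),
                     ref_df = unname(st[i, 2]),
                     statistic = unname(st[i, 3]),
                     p = unname(st[i, 4]))
  }
  out
}

run_one <- function(d) {
  # candidate set: indices into tensor_labels per candidate
  cand_specs <- cfg$candidates
  if (is.null(cand_specs)) cand_specs <- list(list())
  fits <- list(); aics <- numeric(0); labels_list <- list()
  for (ci in seq_along(cand_specs)) {
    tidx <- unlist(cand_specs[[ci]])
    labels <- c(smooth_labels, if (length(tidx)) tensor_labels[tidx + 1] else character(0))
    fit <- tryCatch(fit_gam(labels, d), error = function(e) NULL)
    fits[[ci]] <- fit
    labels_list[[ci]] <- labels
    aics <- c(aics, if (is.null(fit)) NA_real_ else AIC(fit))
  }
  if (all(is.na(aics))) stop("all candidate GAM fits failed")
  chosen <- which.min(aics)  # first minimum on ties
  labels <- labels_list[[chosen]]
  fit <- fits[[chosen]]

  trace <- list()
  if (do_stepwise) {
    # "significant" = family-wise significant across the candidate term set
    # (Bonferroni over the m0 smooths of the chosen candidate); multiplicity
    # "none" reverts to the plain per-term threshold.
    multiplicity <- if (is.null(cfg$multiplicity)) "bonferroni" else cfg$multiplicity
    m0 <- length(labels)
    thresh <- if (identical(multiplicity, "bonferroni") && m0 > 0) alpha / m0 else alpha
    repeat {
      tt <- term_table(fit)
      if (length(tt) == 0) break
      ps <- vapply(tt, function(x) x$p, 0.0)
      terms <- vapply(tt, function(x) x$term, "")
      bad <- which(ps >= thresh)
      if (length(bad) == 0) break
      drop_i <- bad[which.max(ps[bad])]  # largest p; first on exact ties
      drop_term <- terms[drop_i]
      trace[[length(trace) + 1]] <- list(dropped = drop_term, p = ps[drop_i])
      labels <- labels[labels != drop_term]
      fit <- fit_gam(labels, d)
    }
  }

  sm <- summary(fit)
  res <- list(
    candidate_aics = as.list(aics),
    chosen_candidate = chosen - 1,
    removal_trace = trace,
    terms = term_table(fit),
    adj_r2 = if (is.null(sm$r.sq)) NA else sm$r.sq,
    dev_expl = sm$dev.expl,
    n = nrow(d)
  )

  # partial-effect predictions of retained smooths on a supplied grid
  if (!is.null(cfg$grid)) {
    preds <- list()
    retained <- vapply(term_table(fit), function(x) x$term, "")
    for (var in names(cfg$grid)) {
      lbl <- paste0("s(", var, ")")
      if (!(lbl %in% retained)) next
      grid_vals <- unlist(cfg$grid[[var]])
      nd <- d[rep(1, length(grid_vals)), , drop = FALSE]
      for (cn in names(nd)) {
        if (is.numeric(nd[[cn]])) nd[[cn]] <- median(d[[cn]], na.rm = TRUE)
      }
      nd[[var]] <- grid_vals
      pt <- predict(fit, newdata = nd, type = "terms")
      col <- which(colnames(pt) == lbl)
      if (length(col) == 1) preds[[var]] <- as.numeric(pt[, col])
    }
    res$grid_effects <- preds
  }
  res
}

if ("replicate" %in% names(dat)) {
  reps <- sort(unique(dat$replicate))
  results <- lapply(reps, function(r) {
    out <- run_one(dat[dat$replicate == r, setdiff(names(dat), "replicate"), drop = FALSE])
    out$replicate <- r
    out
  })
} else {
  results <- list(run_one(dat))
}

write(toJSON(results, auto_unbox = TRUE, digits = 12, na = "null"),
      file.path(dir, "result.json"))
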